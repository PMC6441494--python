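"""Conservation averaging over circRNA bodies and flanks, with
location-matched shuffled backgrounds.

Per-region means are taken over covered bases only (missing scores are never
imputed as zero). Genic-exonic bodies are averaged over exon features only,
consistent with the exon-only mature sequence upstream. Backgrounds are
drawn uniformly from a matched reference: the exonic reference for genic
bodies, the intronic reference for genic flanks, and the whole genome for
intergenic circRNAs. Real and shuffled groups are compared with a Welch
two-sample t-test (Student's pooled variant available).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .circ_annotate import CircRNA
from .io_formats import Annotation, ConservationTrack, GenomicInterval

DEFAULT_FLANK = 200


def region_mean(
    intervals: Sequence[GenomicInterval], track: ConservationTrack
) -> Tuple[float, int]:
    """Mean score over all covered bases of the union of the intervals.

    Returns (mean, n_covered); the mean is NaN when nothing is covered, and
    such regions should be excluded (and counted) by the caller.
    """
    total = 0.0
    n = 0
    for iv in intervals:
        scores, mask = track.values(iv.chrom, iv.start, iv.end)
        total += float(scores[mask].sum())
        n += int(mask.sum())
    if n == 0:
        return float("nan"), 0
    return total / n, n


def body_mean(circ: CircRNA, track: ConservationTrack) -> Tuple[float, int]:
    """Mean over the circRNA's exon features (introns excluded)."""
    return region_mean([f.interval for f in circ.exon_features], track)


def flanks(
    circ: CircRNA,
    chrom_sizes: Mapping[str, int],
    flank: int = DEFAULT_FLANK,
) -> Dict[str, Optional[GenomicInterval]]:
    """Strand-aware 200-bp (default) upstream/downstream flanks.

    Upstream is the 5' side of the transcribed strand. Flanks are clipped at
    chromosome ends; a fully clipped flank is None. The returned intervals
    carry their actual (possibly shortened) lengths.
    """
    span = circ.span
    size = chrom_sizes[span.chrom]
    left_start = max(0, span.start - flank)
    left = (
        GenomicInterval(span.chrom, left_start, span.start, span.strand)
        if left_start < span.start and span.start > 0
        else None
    )
    right_end = min(size, span.end + flank)
    right = (
        GenomicInterval(span.chrom, span.end, right_end, span.strand)
        if span.end < right_end
        else None
    )
    if span.strand == "-":
        return {"upstream": right, "downstream": left}
    return {"upstream": left, "downstream": right}


def shuffle_matched(
    length: int,
    reference_blocks: Mapping[str, Sequence[Tuple[int, int]]],
    rng: np.random.Generator,
    strand: str = ".",
) -> GenomicInterval:
    """A random interval of the given length, uniform over all feasible
    placements inside the reference blocks."""
    placements: List[Tuple[str, int, int]] = []  # (chrom, block start, n_starts)
    for chrom in sorted(reference_blocks):
        for s, e in reference_blocks[chrom]:
            n = (e - s) - length + 1
            if n > 0:
                placements.append((chrom, s, n))
    if not placements:
        raise ValueError(
            f"no reference block can host a region of length {length}"
        )
    weights = np.array([p[2] for p in placements], dtype=float)
    chrom, block_start, n = placements[rng.choice(len(placements), p=weights / weights.sum())]
    start = block_start + int(rng.integers(0, n))
    return GenomicInterval(chrom, start, start + length, strand)


def matched_references(
    annotation: Annotation, chrom_sizes: Mapping[str, int]
) -> Dict[str, Dict[str, List[Tuple[int, int]]]]:
    """Reference block sets for background shuffling: merged exons, merged
    introns, and whole chromosomes."""
    whole = {c: [(0, n)] for c, n in chrom_sizes.items()}
    gene_body: Dict[str, List[Tuple[int, int]]] = {}
    for gene in annotation.genes.values():
        gene_body.setdefault(gene.chrom, []).append(gene.span)
    return {
        "exonic": annotation.exonic_blocks(),
        "intronic": annotation.intronic_blocks(),
        "gene_body": {c: sorted(b) for c, b in gene_body.items()},
        "genome": whole,
    }


def reference_for(circ_class: str, region_kind: str) -> str:
    """Which reference a shuffled counterpart is drawn from.

    Genic bodies shuffle within exons, genic flanks within introns;
    intergenic (and antisense) regions shuffle over the whole genome.
    """
    if circ_class == "genic_exonic":
        return "exonic" if region_kind == "body" else "intronic"
    if circ_class == "genic_other":
        # spans exons and introns alike, so match against whole gene bodies
        return "gene_body" if region_kind == "body" else "intronic"
    return "genome"


@dataclass
class ConservationResult:
    group: str
    real_means: np.ndarray
    shuffled_means: np.ndarray
    n_excluded: int
    t: float
    df: float
    p: float

    @property
    def real_mean(self) -> float:
        return float(np.mean(self.real_means)) if len(self.real_means) else float("nan")

    @property
    def shuffled_mean(self) -> float:
        return float(np.mean(self.shuffled_means)) if len(self.shuffled_means) else float("nan")


def compare(
    real_means: Sequence[float],
    shuffled_means: Sequence[float],
    welch: bool = True,
) -> Tuple[float, float, float]:
    """Two-sided t-test on per-region means; returns (t, df, p).

    Welch (unequal variances) by default. Two identical zero-variance groups
    give t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(real_means, dtype=float)
    b = np.asarray(shuffled_means, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two regions per group")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(getattr(res, "df", len(a) + len(b) - 2))
    return float(res.statistic), df, float(res.pvalue)


def conservation_analysis(
    circs: Sequence[CircRNA],
    track: ConservationTrack,
    annotation: Annotation,
    chrom_sizes: Mapping[str, int],
    flank: int = DEFAULT_FLANK,
    seed: Optional[int] = None,
    welch: bool = True,
    draws: int = 1,
) -> List[ConservationResult]:
    """Body and flank conservation versus class-matched shuffled backgrounds.

    CircRNAs are grouped into genic vs intergenic-like (antisense +
    intergenic); each group yields a body result and a flank result. One
    shuffled counterpart per real region per draw; with draws > 1 the
    per-region shuffled means are averaged over draws.
    """
    rng = np.random.default_rng(seed)
    refs = matched_references(annotation, chrom_sizes)
    groups = {
        "genic_body": [], "genic_flank": [],
        "intergenic_body": [], "intergenic_flank": [],
    }  # type: Dict[str, List[Tuple[CircRNA, str, List[GenomicInterval]]]]
    for circ in circs:
        genic = circ.circ_class in ("genic_exonic", "genic_other")
        prefix = "genic" if genic else "intergenic"
        groups[f"{prefix}_body"].append(
            (circ, "body", [f.interval for f in circ.exon_features])
        )
        for iv in flanks(circ, chrom_sizes, flank).values():
            if iv is not None:
                groups[f"{prefix}_flank"].append((circ, "flank", [iv]))
    results: List[ConservationResult] = []
    for group, entries in groups.items():
        if len(entries) < 2:
            continue
        real: List[float] = []
        shuffled: List[float] = []
        n_excluded = 0
        for circ, kind, ivs in entries:
            mean, n_cov = region_mean(ivs, track)
            if n_cov == 0:
                n_excluded += 1
                continue
            ref = refs[reference_for(circ.circ_class, kind)]
            if not ref:
                ref = refs["genome"]
            draws_means = []
            for _ in range(draws):
                # one length-matched placement per constituent interval, so a
                # multi-exon body shuffles exon-by-exon within the reference
                sivs = [shuffle_matched(iv.length, ref, rng) for iv in ivs]
                smean, sn = region_mean(sivs, track)
                if sn > 0:
                    draws_means.append(smean)
            if not draws_means:
                n_excluded += 1
                continue
            real.append(mean)
            shuffled.append(float(np.mean(draws_means)))
        if len(real) < 2:
            continue
        t, df, p = compare(real, shuffled, welch=welch)
        results.append(ConservationResult(
            group, np.array(real), np.array(shuffled), n_excluded, t, df, p
        ))
    return results
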