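"""Classification and decomposition of backsplice junctions.

A junction is *genic-exonic* when both of its ends coincide exactly (to the
base, after coordinate normalization) with annotated exon boundaries of one
same-strand gene; *genic-other* when it overlaps a same-strand gene but the
boundary condition fails; *antisense* when it overlaps genes only on the
opposite strand; *intergenic* otherwise. Genic-exonic circRNAs are decomposed
into alternating exon/intron features from the union of the host gene's
exons; every other class is treated as a single exon covering the span.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .io_formats import Annotation, Gene, GenomicInterval, JunctionCall
from ._seq import revcomp

logger = logging.getLogger(__name__)

CIRC_CLASSES = ("genic_exonic", "genic_other", "antisense", "intergenic")

#: reciprocal-overlap levels reported by catalog comparison, tightest first
DEFAULT_OVERLAP_LEVELS = (1.0, 0.9, 0.75, 0.5)


@dataclass(frozen=True)
class Feature:
    """One exon or intron feature of a circRNA."""

    interval: GenomicInterval
    kind: str  # "exon" | "intron"
    circ_id: str
    ordinal: int

    @property
    def feature_id(self) -> str:
        return f"{self.circ_id}|{self.kind}{self.ordinal}"


@dataclass
class CircRNA:
    circ_id: str
    span: GenomicInterval
    circ_class: str
    host_gene: Optional[str] = None
    features: List[Feature] = field(default_factory=list)
    sequence: Optional[str] = None
    support: int = 0

    @property
    def exon_features(self) -> List[Feature]:
        return [f for f in self.features if f.kind == "exon"]

    @property
    def exonic_length(self) -> int:
        return sum(f.interval.length for f in self.exon_features)


def _boundary_matches(span: GenomicInterval, gene: Gene) -> int:
    """Number of circRNA ends (0..2) that coincide with exon-union boundaries."""
    blocks = gene.exon_union()
    starts = {b[0] for b in blocks}
    ends = {b[1] for b in blocks}
    return int(span.start in starts) + int(span.end in ends)


def choose_host(span: GenomicInterval, candidates: Sequence[Gene]) -> Optional[Gene]:
    """Deterministic host-gene choice: most matched boundaries, then
    lexicographically smaller gene id."""
    if not candidates:
        return None
    return min(candidates, key=lambda g: (-_boundary_matches(span, g), g.gene_id))


def classify(
    junction: GenomicInterval, annotation: Annotation
) -> Tuple[str, Optional[Gene]]:
    """Classify a junction span against the annotation.

    Returns ``(circ_class, host_gene)``; the host is None for antisense and
    intergenic calls. A junction on a chromosome absent from the annotation
    is intergenic (with a logged warning).
    """
    if junction.chrom not in annotation.chromosomes:
        logger.warning(
            "junction %s:%d-%d on chromosome absent from annotation; "
            "classifying intergenic",
            junction.chrom, junction.start, junction.end,
        )
        return "intergenic", None
    overlapping = annotation.genes_overlapping(junction.chrom, junction.start, junction.end)
    same = [g for g in overlapping if g.strand == junction.strand]
    if same:
        host = choose_host(junction, same)
        if _boundary_matches(junction, host) == 2:
            return "genic_exonic", host
        return "genic_other", host
    if overlapping:
        return "antisense", None
    return "intergenic", None


def decompose(
    circ_id: str,
    span: GenomicInterval,
    circ_class: str,
    host_gene: Optional[Gene],
) -> List[Feature]:
    """Tile the span with exon/intron features.

    Genic-exonic circRNAs take the host gene's exon-union blocks clipped to
    the span as exons and the gaps between them as introns; all other classes
    become a single exon covering the span.
    """
    if circ_class != "genic_exonic":
        return [Feature(replace(span), "exon", circ_id, 1)]
    if host_gene is None:
        raise ValueError(f"{circ_id}: genic_exonic circRNA without host gene")
    blocks = [
        (max(s, span.start), min(e, span.end))
        for s, e in host_gene.exon_union()
        if s < span.end and e > span.start
    ]
    if not blocks:
        raise ValueError(f"{circ_id}: no annotated exon inside genic_exonic span")
    features: List[Feature] = []
    n_exon = n_intron = 0
    prev_end = None
    for s, e in blocks:
        if prev_end is not None and s > prev_end:
            n_intron += 1
            features.append(
                Feature(GenomicInterval(span.chrom, prev_end, s, span.strand),
                        "intron", circ_id, n_intron)
            )
        n_exon += 1
        features.append(
            Feature(GenomicInterval(span.chrom, s, e, span.strand), "exon", circ_id, n_exon)
        )
        prev_end = e
    return features


def reconstruct_sequence(circ: CircRNA, genome: Mapping[str, str]) -> str:
    """Mature sequence: exon features concatenated in transcription order.

    Introns are excluded. Minus-strand circRNAs are reverse-complemented; the
    returned string is one pass around the circle starting at the most 5'
    exonic base.
    """
    chrom_seq = genome.get(circ.span.chrom)
    if chrom_seq is None:
        raise ValueError(f"{circ.circ_id}: chromosome {circ.span.chrom} not in genome")
    parts = []
    for f in circ.exon_features:
        if f.interval.end > len(chrom_seq):
            raise ValueError(
                f"{circ.circ_id}: feature end {f.interval.end} beyond chromosome "
                f"{circ.span.chrom} length {len(chrom_seq)}"
            )
        parts.append(chrom_seq[f.interval.start : f.interval.end])
    seq = "".join(parts)
    if circ.span.strand == "-":
        seq = revcomp(seq)
    return seq.upper()


def assign_ids(
    spans: Sequence[GenomicInterval], prefix: str = "CiCo_sim_circ"
) -> List[str]:
    """Stable ids: sort by (chrom, start, end, strand), zero-padded ordinals."""
    order = sorted(range(len(spans)), key=lambda i: (
        spans[i].chrom, spans[i].start, spans[i].end, spans[i].strand))
    ids = [""] * len(spans)
    for ordinal, i in enumerate(order, start=1):
        ids[i] = f"{prefix}_{ordinal:06d}"
    return ids


def annotate_junctions(
    junctions: Sequence[JunctionCall],
    annotation: Annotation,
    genome: Optional[Mapping[str, str]] = None,
    prefix: str = "CiCo_sim_circ",
) -> List[CircRNA]:
    """Classify, decompose and (optionally) reconstruct every junction call.

    No read-support filter is applied: all records are kept.
    """
    spans = [j.interval for j in junctions]
    ids = assign_ids(spans, prefix=prefix)
    circs: List[CircRNA] = []
    for junction, circ_id in zip(junctions, ids):
        circ_class, host = classify(junction.interval, annotation)
        features = decompose(circ_id, junction.interval, circ_class, host)
        circ = CircRNA(
            circ_id=circ_id,
            span=junction.interval,
            circ_class=circ_class,
            host_gene=host.gene_id if host else None,
            features=features,
            support=junction.support,
        )
        if genome is not None:
            circ.sequence = reconstruct_sequence(circ, genome)
        circs.append(circ)
    circs.sort(key=lambda c: c.circ_id)
    return circs


@dataclass(frozen=True)
class CatalogHit:
    known: bool
    level: Optional[float]  # maximal reciprocal fraction passed, or None
    catalog_name: Optional[str] = None


def catalog_overlap(
    circs: Sequence[CircRNA],
    catalog: Sequence[GenomicInterval],
    levels: Sequence[float] = DEFAULT_OVERLAP_LEVELS,
    single_nucleotide: bool = False,
    catalog_names: Optional[Sequence[str]] = None,
) -> Dict[str, CatalogHit]:
    """Compare circRNAs with an external catalog by reciprocal overlap.

    At level ``f`` a circRNA is *known* iff some catalog interval on the same
    chromosome satisfies both overlap/len(circ) >= f and
    overlap/len(catalog) >= f. In single-nucleotide mode any >= 1 bp overlap
    counts. The maximal level passed is reported per circRNA.
    """
    for f in levels:
        if not (0 < f <= 1):
            raise ValueError(f"reciprocal fraction must be in (0, 1], got {f}")
    names = list(catalog_names) if catalog_names is not None else [""] * len(catalog)
    by_chrom: Dict[str, List[Tuple[GenomicInterval, str]]] = {}
    for iv, nm in zip(catalog, names):
        by_chrom.setdefault(iv.chrom, []).append((iv, nm))
    out: Dict[str, CatalogHit] = {}
    for circ in circs:
        best_frac = 0.0
        best_any = False
        best_name: Optional[str] = None
        for iv, nm in by_chrom.get(circ.span.chrom, []):
            ov = circ.span.overlap(iv)
            if ov <= 0:
                continue
            frac = min(ov / circ.span.length, ov / iv.length)
            if not best_any or frac > best_frac:
                best_any, best_frac, best_name = True, frac, nm
        if single_nucleotide:
            out[circ.circ_id] = CatalogHit(best_any, None, best_name if best_any else None)
            continue
        passed = [f for f in levels if best_frac >= f]
        level = max(passed) if passed else None
        out[circ.circ_id] = CatalogHit(level is not None, level,
                                       best_name if level is not None else None)
    return out
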