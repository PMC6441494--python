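"""Synthetic dataset generator with a machine-readable truth manifest.

Emulates a three-population x three-replicate sorted-cell design: a small
random genome with planted gene models, backsplice junction calls of the
four circRNA classes (97% genic-exonic by default), per-sample read
intervals drawn around planted expression levels, a conservation track with
planted elevation over circRNA bodies and flanks, a miRNA library with
planted seed sites, codon-biased planted ORFs, and correlated linear-host
expression tables. Every planted quantity is recorded in ``truth.json`` so
each downstream stage can be scored against ground truth.

All randomness flows from a single integer seed; the same (config, seed)
pair reproduces the bundle byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import circ_annotate, mirna_seeds, orf_cai
from ._seq import complement, revcomp
from .circ_annotate import CircRNA, Feature
from .codon_tables import mouse_codon_usage
from .conservation import flanks as circ_flanks
from .io_formats import (
    Annotation,
    ConservationTrack,
    CodonUsageTable,
    Gene,
    GenomicInterval,
    JunctionCall,
    SYNONYMOUS_FAMILIES,
    Transcript,
    write_annotation,
    write_codon_usage,
    write_fasta,
    write_junction_calls,
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

CLASS_ORDER = ("genic_exonic", "genic_other", "antisense", "intergenic")


@dataclass
class SimConfig:
    """Generator settings. Defaults define the study conditions of the
    default bundle (two 500-kb chromosomes, 300 genes, 150 circRNAs,
    three populations x three replicates at 50k reads per sample)."""

    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 300
    n_circ: int = 150
    class_mix: Dict[str, float] = field(default_factory=lambda: {
        "genic_exonic": 0.97, "genic_other": 0.01,
        "antisense": 0.01, "intergenic": 0.01,
    })
    populations: Tuple[str, ...] = ("PP", "DP", "N")
    n_replicates: int = 3
    library_size: int = 50_000
    noise: str = "nb"  # "nb" | "poisson" | "none"
    nb_dispersion: float = 0.05
    read_length: int = 50
    frac_expressed: float = 0.8
    trajectory_mix: Dict[str, float] = field(default_factory=lambda: {
        "FF": 0.40, "UU": 0.10, "DD": 0.10, "UD": 0.10, "DU": 0.10,
        "UF": 0.05, "FU": 0.05, "DF": 0.05, "FD": 0.05,
    })
    up_factor: float = 2.0
    down_factor: float = 0.4
    base_count_range: Tuple[float, float] = (50.0, 500.0)
    n_mirnas: int = 20
    mirna_length: int = 22
    n_seed_circs: int = 8
    max_seed_sites: int = 5
    n_orf_circs: int = 10
    orf_length: int = 300
    body_elevation: float = 0.5
    flank_elevation: float = 0.25
    conservation_base: float = 0.0
    conservation_noise_sd: float = 0.2
    flank_size: int = 200
    linear_correlation: float = 0.8
    frac_as_genes: float = 0.2
    opposite_rate: float = 0.005
    id_prefix: str = "CiCo_sim_circ"

    @property
    def samples(self) -> List[str]:
        return [f"{pop}_{r}" for pop in self.populations
                for r in range(1, self.n_replicates + 1)]

    @property
    def design(self) -> Dict[str, str]:
        return {f"{pop}_{r}": pop for pop in self.populations
                for r in range(1, self.n_replicates + 1)}


@dataclass
class Bundle:
    config: SimConfig
    seed: int
    genome: Dict[str, str]
    chrom_sizes: Dict[str, int]
    annotation: Annotation
    junctions: List[JunctionCall]
    reads: Dict[str, List[GenomicInterval]]
    library_sizes: Dict[str, int]
    design: Dict[str, str]
    track: ConservationTrack
    mirnas: Dict[str, str]
    codon_usage: CodonUsageTable
    linear_rpkm: pd.DataFrame
    isoform_rpkm: pd.DataFrame
    exon_fc: pd.DataFrame
    manifest: Dict[str, object]
    truth_circs: List[CircRNA]

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        write_annotation(self.annotation, os.path.join(outdir, "annotation.gtf"))
        write_junction_calls(self.junctions, os.path.join(outdir, "junctions.bed"))
        reads_dir = os.path.join(outdir, "reads")
        os.makedirs(reads_dir, exist_ok=True)
        for sample, reads in self.reads.items():
            with open(os.path.join(reads_dir, f"{sample}.bed"), "w") as fh:
                for i, r in enumerate(reads):
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t0\t{r.strand}\n")
        self.track.to_bedgraph(os.path.join(outdir, "phylop.bedgraph"))
        write_fasta(self.mirnas, os.path.join(outdir, "mirnas.fa"))
        write_codon_usage(self.codon_usage, os.path.join(outdir, "codon_usage.tsv"))
        self.linear_rpkm.to_csv(os.path.join(outdir, "linear_rpkm.tsv"), sep="\t")
        self.isoform_rpkm.to_csv(os.path.join(outdir, "isoform_rpkm.tsv"), sep="\t")
        self.exon_fc.to_csv(os.path.join(outdir, "exon_fc.tsv"), sep="\t")
        with open(os.path.join(outdir, "design.tsv"), "w") as fh:
            fh.write("sample\tpopulation\n")
            for sample, pop in self.design.items():
                fh.write(f"{sample}\t{pop}\n")
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")


def largest_remainder(total: int, fractions: Mapping[str, float]) -> Dict[str, int]:
    """Deterministic integer allocation: floor each share, then hand the
    remaining units to the largest fractional parts (ties by key order)."""
    keys = list(fractions)
    raw = {k: total * fractions[k] for k in keys}
    out = {k: int(math.floor(raw[k])) for k in keys}
    remainder = total - sum(out.values())
    order = sorted(keys, key=lambda k: (-(raw[k] - out[k]), keys.index(k)))
    for k in order[:remainder]:
        out[k] += 1
    return out


# ---------------------------------------------------------------------------
# Sequence-level planting
# ---------------------------------------------------------------------------

def plant_seed_sites(
    sequence: str,
    mirna: str,
    n: int,
    category: str = "8mer",
    rng: Optional[np.random.Generator] = None,
    junction_site: bool = False,
    max_tries: int = 30,
) -> str:
    """Edit a mature (DNA) sequence so it carries exactly ``n`` seed sites of
    the requested category for ``mirna`` and no other site for that miRNA.

    Pre-existing sites are scrambled first; the result is verified with the
    scanner's own circular search. With ``junction_site`` one of the sites
    straddles the backsplice junction. Raises when the sites cannot be
    placed without creating extras.
    """
    if category not in mirna_seeds.SEED_CATEGORIES:
        raise ValueError(f"unknown seed category {category!r}")
    if n == 0:
        return sequence
    rng = rng if rng is not None else np.random.default_rng()
    seq = list(sequence.upper())
    L = len(seq)
    if n * 12 + 16 > L:
        raise ValueError(f"cannot place {n} sites in a {L}-nt sequence")
    m_rna = mirna.upper().replace("T", "U")
    core = revcomp(m_rna[1:7], rna=True).replace("U", "T")
    m8_partner = complement(m_rna[7], rna=True).replace("U", "T")
    non_m8 = next(b for b in "ACGT" if b != m8_partner)
    non_a = "C"
    want_m8 = category in ("8mer", "7mer-m8")
    want_a1 = category in ("8mer", "7mer-A1")
    for attempt in range(max_tries):
        work = seq.copy()
        _scramble_sites(work, m_rna, rng)
        positions: List[int] = []
        if junction_site:
            positions.append(L - 3)  # core straddles the junction
        while len(positions) < n:
            p = int(rng.integers(0, L))
            if all(min((p - q) % L, (q - p) % L) >= 12 for q in positions):
                positions.append(p)
        for p in positions:
            work[(p - 1) % L] = m8_partner if want_m8 else non_m8
            for k, base in enumerate(core):
                work[(p + k) % L] = base
            work[(p + 6) % L] = "A" if want_a1 else non_a
        out = "".join(work)
        matches = mirna_seeds.scan(out, m_rna, circular=True)
        if len(matches) == n and all(mm.category == category for mm in matches):
            return out
    raise ValueError(
        f"could not place {n} {category} sites without creating extras"
    )


def _scramble_sites(work: List[str], mirna_rna: str, rng: np.random.Generator,
                    max_rounds: int = 20) -> None:
    """Destroy all existing seed cores for this miRNA by point mutation."""
    L = len(work)
    for _ in range(max_rounds):
        matches = mirna_seeds.scan("".join(work), mirna_rna, circular=True)
        if not matches:
            return
        for mm in matches:
            pos = (mm.start + 3) % L
            current = work[pos]
            work[pos] = next(b for b in "ACGT" if b != current)
    raise ValueError("could not scramble pre-existing seed sites")


def plant_orf(
    sequence: str,
    usage: CodonUsageTable,
    orf_length: int,
    rng: np.random.Generator,
    optimal_prob: float = 0.9,
) -> Tuple[str, int]:
    """Insert a codon-biased ORF (ATG ... stop, ``orf_length`` nt total) at a
    random position of the mature sequence; returns (edited sequence, start)."""
    if orf_length % 3 != 0 or orf_length < 9:
        raise ValueError("ORF length must be a multiple of 3, at least 9")
    L = len(sequence)
    if orf_length + 6 > L:
        raise ValueError(f"ORF of {orf_length} nt does not fit in {L} nt")
    w = orf_cai.relative_adaptiveness(usage)
    families = list(SYNONYMOUS_FAMILIES.values())
    codons = ["ATG"]
    n_codons = orf_length // 3 - 2
    for _ in range(n_codons):
        fam = families[int(rng.integers(0, len(families)))]
        if rng.random() < optimal_prob:
            codon = max(fam, key=lambda c: w[c])
        else:
            codon = fam[int(rng.integers(0, len(fam)))]
        codons.append(codon)
    codons.append("TAA")
    orf = "".join(codons)
    start = int(rng.integers(3, L - orf_length - 3))
    return sequence[:start] + orf + sequence[start + orf_length:], start


def generate_conservation_track(
    chrom_sizes: Mapping[str, int],
    conserved_intervals: Sequence[GenomicInterval],
    elevation: float,
    base_level: float = 0.0,
    noise_sd: float = 0.2,
    seed: Optional[int] = None,
    masked_intervals: Sequence[GenomicInterval] = (),
) -> ConservationTrack:
    """Per-base scores = base + elevation * [inside a conserved interval]
    + Gaussian noise; masked intervals carry no score."""
    rng = np.random.default_rng(seed)
    tiers = [(iv, elevation) for iv in conserved_intervals]
    return _noise_track(chrom_sizes, tiers, base_level, noise_sd, rng, masked_intervals)


def _noise_track(chrom_sizes, tiers, base, sd, rng, masked=()):
    scores: Dict[str, np.ndarray] = {}
    masks: Dict[str, np.ndarray] = {}
    for chrom in sorted(chrom_sizes):
        n = chrom_sizes[chrom]
        arr = np.full(n, float(base))
        if sd > 0:
            arr += sd * rng.standard_normal(n)
        scores[chrom] = arr
        masks[chrom] = np.ones(n, dtype=bool)
    for iv, elev in tiers:
        if iv.chrom not in scores or iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(f"conserved interval {iv} outside genome")
        scores[iv.chrom][iv.start : iv.end] += elev
    for iv in masked:
        masks[iv.chrom][iv.start : iv.end] = False
    return ConservationTrack.from_dense(scores, masks)


def correlated_rpkm_pairs(
    n: int,
    rho: float,
    seed: Optional[int] = None,
    log2_mean_x: float = 4.0,
    log2_sd_x: float = 1.5,
    log2_mean_y: float = 6.0,
    log2_sd_y: float = 1.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Bivariate log-normal RPKM pairs with target Pearson correlation
    ``rho`` on the log2 scale."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(max(0.0, 1 - rho * rho)) * rng.standard_normal(n)
    x = np.exp2(log2_mean_x + log2_sd_x * z1)
    y = np.exp2(log2_mean_y + log2_sd_y * z2)
    return x, y


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate_dataset(config: Optional[SimConfig] = None, seed: int = 0) -> Bundle:
    """Generate the full bundle plus truth manifest (see module docstring)."""
    config = config if config is not None else SimConfig()
    rng = np.random.default_rng(seed)
    chrom_sizes = {
        f"chrS{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    genome_arr = {
        c: _BASE_BYTES[rng.integers(0, 4, size=n)].copy()
        for c, n in sorted(chrom_sizes.items())
    }

    genes, gaps = _place_genes(config, chrom_sizes, rng)
    annotation = Annotation({g.gene_id: g for g in genes})

    circs, class_of = _place_circs(config, genes, gaps, rng)
    # expression design
    n_expr = int(round(config.frac_expressed * config.n_circ))
    order = rng.permutation(len(circs))
    expressed_idx = set(order[:n_expr].tolist())
    label_counts = largest_remainder(n_expr, config.trajectory_mix)
    labels_pool = [lab for lab, k in label_counts.items() for _ in range(k)]
    labels_pool = [labels_pool[i] for i in rng.permutation(len(labels_pool))]
    lo, hi = config.base_count_range
    factor = {"U": config.up_factor, "D": config.down_factor, "F": 1.0}
    traj: Dict[int, Optional[str]] = {}
    base_counts: Dict[int, float] = {}
    it = iter(labels_pool)
    for i in range(len(circs)):
        if i in expressed_idx:
            traj[i] = next(it)
            base_counts[i] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            traj[i] = None
            base_counts[i] = 0.0

    # per-feature expected counts and noisy realizations
    features = [f for c in circs for f in c.features]
    feat_index = {f.feature_id: k for k, f in enumerate(features)}
    expected = np.zeros((len(features), len(config.populations)))
    for i, circ in enumerate(circs):
        if traj[i] is None:
            continue
        mults = np.cumprod([1.0] + [factor[ch] for ch in traj[i]])
        exon_feats = circ.exon_features
        total_len = sum(f.interval.length for f in exon_feats)
        for f in exon_feats:
            share = f.interval.length / total_len
            expected[feat_index[f.feature_id]] = base_counts[i] * share * mults
    counts = _draw_counts(expected, config, rng)
    counts_df = pd.DataFrame(
        counts, index=[f.feature_id for f in features], columns=config.samples
    )

    reads = _make_reads(config, circs, features, counts_df, gaps, chrom_sizes, rng)
    library_sizes = {s: config.library_size for s in config.samples}

    # realized per-population mean RPKM at the circRNA (meta-feature) level
    rpkm_pop: Dict[str, Dict[str, float]] = {}
    r_factor = config.library_size * 1e-6
    for i, circ in enumerate(circs):
        ids = [f.feature_id for f in circ.exon_features]
        meta = counts_df.loc[ids].sum(axis=0)
        l_factor = circ.exonic_length * 1e-3
        per_pop = {}
        for pop in config.populations:
            cols = [s for s in config.samples if config.design[s] == pop]
            per_pop[pop] = float(meta[cols].mean() / (r_factor * l_factor))
        rpkm_pop[circ.circ_id] = per_pop

    # sequence-level planting (ORFs, then seed sites, on disjoint circRNAs)
    usage = mouse_codon_usage()
    mirnas = _make_mirnas(config, rng)
    eligible = [
        i for i in range(len(circs))
        if traj[i] is not None and class_of[i] == "genic_exonic"
        and circs[i].exonic_length >= max(config.orf_length + 60, 200)
    ]
    eligible = [eligible[j] for j in rng.permutation(len(eligible))]
    orf_set = eligible[: config.n_orf_circs]
    seed_set = eligible[config.n_orf_circs : config.n_orf_circs + config.n_seed_circs]
    orf_truth: Dict[str, Dict[str, object]] = {}
    for i in orf_set:
        circ = circs[i]
        seq = _mature_sequence(circ, genome_arr)
        edited, start = plant_orf(seq, usage, config.orf_length, rng)
        _write_mature(circ, edited, genome_arr)
        found = orf_cai.find_orfs(edited, min_len=150)
        orf_truth[circ.circ_id] = {
            "planted": True, "length": config.orf_length,
            "start": start, "n_found": len(found),
        }
    mirna_ids = sorted(mirnas)
    seed_truth: Dict[str, Dict[str, Dict[str, object]]] = {}
    categories = list(mirna_seeds.SEED_CATEGORIES)
    for j, i in enumerate(seed_set):
        circ = circs[i]
        mirna_id = mirna_ids[j % len(mirna_ids)]
        n_sites = int(rng.integers(1, config.max_seed_sites + 1))
        category = categories[int(rng.integers(0, len(categories)))]
        junction = j == 0  # one planted site straddles the backsplice junction
        seq = _mature_sequence(circ, genome_arr)
        edited = plant_seed_sites(
            seq, mirnas[mirna_id], n_sites, category=category, rng=rng,
            junction_site=junction,
        )
        _write_mature(circ, edited, genome_arr)
        seed_truth[circ.circ_id] = {
            mirna_id: {"category": category, "n": n_sites,
                       "junction_spanning": junction}
        }

    genome = {c: arr.tobytes().decode("ascii") for c, arr in genome_arr.items()}
    for circ in circs:
        circ.sequence = circ_annotate.reconstruct_sequence(circ, genome)

    # conservation track with planted elevation over bodies and flanks
    tiers: List[Tuple[GenomicInterval, float]] = []
    for circ in circs:
        for f in circ.exon_features:
            tiers.append((f.interval, config.body_elevation))
        for iv in circ_flanks(circ, chrom_sizes, config.flank_size).values():
            if iv is not None:
                tiers.append((iv, config.flank_elevation))
    masked = [
        GenomicInterval(c, 0, 500) for c in sorted(chrom_sizes)
    ] + [
        GenomicInterval(c, chrom_sizes[c] - 500, chrom_sizes[c])
        for c in sorted(chrom_sizes)
    ]
    track = _noise_track(
        chrom_sizes, tiers, config.conservation_base,
        config.conservation_noise_sd, rng, masked,
    )

    linear_rpkm, isoform_rpkm, exon_fc, pair_truth = _linear_tables(
        config, circs, class_of, traj, rpkm_pop, genes, rng
    )

    junctions = _make_junctions(circs, traj, rng)

    class_counts = {k: 0 for k in CLASS_ORDER}
    for cls in class_of:
        class_counts[cls] += 1
    trajectory_counts: Dict[str, int] = {}
    for lab in traj.values():
        if lab is not None:
            trajectory_counts[lab] = trajectory_counts.get(lab, 0) + 1

    circ_truth = {}
    for i, circ in enumerate(circs):
        circ_truth[circ.circ_id] = {
            "class": class_of[i],
            "host_gene": circ.host_gene,
            "span": [circ.span.chrom, circ.span.start, circ.span.end, circ.span.strand],
            "exons": [[f.interval.start, f.interval.end] for f in circ.exon_features],
            "introns": [[f.interval.start, f.interval.end]
                        for f in circ.features if f.kind == "intron"],
            "expressed": traj[i] is not None,
            "trajectory": traj[i],
            "base_count": base_counts[i],
            "rpkm": rpkm_pop[circ.circ_id],
            "seeds": seed_truth.get(circ.circ_id, {}),
            "orf": orf_truth.get(circ.circ_id, {"planted": False}),
            "conservation_elevation": config.body_elevation,
        }
    manifest: Dict[str, object] = {
        "seed": seed,
        "config": dataclasses.asdict(config),
        "samples": config.design,
        "library_sizes": library_sizes,
        "rpkm_threshold": 3.5,
        "n_putative": len(circs),
        "n_expressed": n_expr,
        "class_counts": class_counts,
        "trajectory_counts": trajectory_counts,
        "circs": circ_truth,
        "linear": {
            "target_correlation": config.linear_correlation,
            "pairs": sorted(pair_truth),
        },
        "concordance": pair_truth,
    }
    return Bundle(
        config=config, seed=seed, genome=genome, chrom_sizes=chrom_sizes,
        annotation=annotation, junctions=junctions, reads=reads,
        library_sizes=library_sizes, design=config.design, track=track,
        mirnas=mirnas, codon_usage=usage, linear_rpkm=linear_rpkm,
        isoform_rpkm=isoform_rpkm, exon_fc=exon_fc, manifest=manifest,
        truth_circs=circs,
    )


# ---------------------------------------------------------------------------
# Generator internals
# ---------------------------------------------------------------------------

def _place_genes(config, chrom_sizes, rng):
    chroms = sorted(chrom_sizes)
    per_chrom = largest_remainder(config.n_genes, {c: 1 / len(chroms) for c in chroms})
    genes: List[Gene] = []
    gaps: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    idx = 0
    for chrom in chroms:
        size = chrom_sizes[chrom]
        cursor = 1000
        placed = 0
        while placed < per_chrom[chrom]:
            gap = int(rng.integers(200, 601))
            gap_start = cursor
            cursor += gap
            n_ex = int(rng.integers(3, 7))
            exon_lens = rng.integers(120, 301, size=n_ex)
            intron_lens = rng.integers(150, 451, size=n_ex - 1)
            length = int(exon_lens.sum() + intron_lens.sum())
            if cursor + length > size - 1000:
                raise ValueError(
                    f"infeasible config: cannot place {per_chrom[chrom]} genes "
                    f"on a {size}-bp chromosome"
                )
            exons = []
            pos = cursor
            for k in range(n_ex):
                exons.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < n_ex - 1:
                    pos += int(intron_lens[k])
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene = Gene(f"SIMG{idx:05d}", chrom, strand, name=f"Gene{idx}")
            gene.transcripts["SIMT%05d_1" % idx] = Transcript(
                "SIMT%05d_1" % idx, exons=list(exons))
            if n_ex >= 4 and rng.random() < config.frac_as_genes:
                skip = int(rng.integers(1, n_ex - 1))
                gene.transcripts["SIMT%05d_2" % idx] = Transcript(
                    "SIMT%05d_2" % idx,
                    exons=[e for k, e in enumerate(exons) if k != skip])
            genes.append(gene)
            gaps[chrom].append((gap_start + 10, cursor - 10))
            cursor = pos
            placed += 1
        if cursor + 40 < size - 1000:
            gaps[chrom].append((cursor + 10, size - 1000))
    return genes, gaps


def _place_circs(config, genes, gaps, rng):
    class_counts = largest_remainder(
        config.n_circ, {k: config.class_mix.get(k, 0.0) for k in CLASS_ORDER})
    gene_order = [genes[i] for i in rng.permutation(len(genes))]
    need_genes = (class_counts["genic_exonic"] + class_counts["genic_other"]
                  + class_counts["antisense"])
    if need_genes > len(genes):
        raise ValueError("infeasible config: more genic circRNAs than genes")
    spans: List[GenomicInterval] = []
    classes: List[str] = []
    hosts: List[Optional[Gene]] = []
    gi = 0
    for _ in range(class_counts["genic_exonic"]):
        gene = gene_order[gi]; gi += 1
        exons = gene.transcripts[sorted(gene.transcripts)[0]].exons
        i0 = int(rng.integers(0, len(exons)))
        span_n = int(rng.integers(1, min(3, len(exons) - i0) + 1))
        spans.append(GenomicInterval(
            gene.chrom, exons[i0][0], exons[i0 + span_n - 1][1], gene.strand))
        classes.append("genic_exonic")
        hosts.append(gene)
    for _ in range(class_counts["genic_other"]):
        gene = gene_order[gi]; gi += 1
        exons = gene.transcripts[sorted(gene.transcripts)[0]].exons
        d1 = int(rng.integers(5, 51))
        d2 = int(rng.integers(5, 51))
        spans.append(GenomicInterval(
            gene.chrom, exons[0][0] + d1, exons[-1][1] - d2, gene.strand))
        classes.append("genic_other")
        hosts.append(gene)
    for _ in range(class_counts["antisense"]):
        gene = gene_order[gi]; gi += 1
        s, e = gene.span
        start = s + int(rng.integers(10, max(11, (e - s) // 3)))
        length = int(rng.integers(200, 601))
        end = min(e - 10, start + length)
        strand = "-" if gene.strand == "+" else "+"
        spans.append(GenomicInterval(gene.chrom, start, end, strand))
        classes.append("antisense")
        hosts.append(None)
    all_gaps = [(c, s, e) for c, blocks in sorted(gaps.items()) for s, e in blocks
                if e - s >= 260]
    if class_counts["intergenic"] > len(all_gaps):
        raise ValueError("infeasible config: not enough intergenic space")
    picked = rng.choice(len(all_gaps), size=class_counts["intergenic"], replace=False)
    for k in sorted(picked.tolist()):
        chrom, s, e = all_gaps[k]
        length = int(rng.integers(150, min(e - s - 40, 400) + 1))
        start = s + int(rng.integers(0, e - s - length - 20 + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        spans.append(GenomicInterval(chrom, start, start + length, strand))
        classes.append("intergenic")
        hosts.append(None)
    ids = circ_annotate.assign_ids(spans, prefix=config.id_prefix)
    circs: List[CircRNA] = []
    class_of: List[str] = []
    order = sorted(range(len(spans)), key=lambda i: ids[i])
    for i in order:
        span, cls, host, circ_id = spans[i], classes[i], hosts[i], ids[i]
        if cls == "genic_exonic":
            feats = circ_annotate.decompose(circ_id, span, cls, host)
        else:
            feats = [Feature(span, "exon", circ_id, 1)]
        circs.append(CircRNA(
            circ_id=circ_id, span=span, circ_class=cls,
            host_gene=host.gene_id if host else None, features=feats,
        ))
        class_of.append(cls)
    return circs, class_of


def _draw_counts(expected, config, rng):
    n_feat = expected.shape[0]
    out = np.zeros((n_feat, len(config.samples)), dtype=np.int64)
    for j, sample in enumerate(config.samples):
        pop_idx = list(config.populations).index(config.design[sample])
        mu = expected[:, pop_idx]
        if config.noise == "none":
            out[:, j] = np.round(mu).astype(np.int64)
        elif config.noise == "poisson":
            out[:, j] = rng.poisson(mu)
        elif config.noise == "nb":
            shape = 1.0 / config.nb_dispersion
            lam = np.where(mu > 0, rng.gamma(shape, np.maximum(mu, 1e-12) / shape), 0.0)
            out[:, j] = rng.poisson(lam)
        else:
            raise ValueError(f"unknown noise model {config.noise!r}")
    return out


def _make_reads(config, circs, features, counts_df, gaps, chrom_sizes, rng):
    reads: Dict[str, List[GenomicInterval]] = {}
    free_blocks = []
    circ_spans = sorted(
        (c.span.chrom, c.span.start, c.span.end) for c in circs)
    for chrom, blocks in sorted(gaps.items()):
        for s, e in blocks:
            pieces = [(s, e)]
            for cc, cs, ce in circ_spans:
                if cc != chrom:
                    continue
                pieces = [
                    piece for lo, hi in pieces
                    for piece in ((lo, min(hi, cs - 5)), (max(lo, ce + 5), hi))
                    if piece[1] - piece[0] >= config.read_length
                ]
            free_blocks.extend((chrom, lo, hi) for lo, hi in pieces)
    weights = np.array(
        [hi - lo - config.read_length + 1 for _, lo, hi in free_blocks], dtype=float)
    weights /= weights.sum()
    for sample in config.samples:
        sample_reads: List[GenomicInterval] = []
        for feat in features:
            count = int(counts_df.at[feat.feature_id, sample])
            if count == 0:
                continue
            iv = feat.interval
            rl = min(config.read_length, iv.length)
            starts = rng.integers(iv.start, iv.end - rl + 1, size=count)
            sample_reads.extend(
                GenomicInterval(iv.chrom, int(s), int(s) + rl, iv.strand)
                for s in starts
            )
        n_bg = config.library_size - len(sample_reads)
        if n_bg < 0:
            raise ValueError(
                "infeasible config: planted counts exceed the library size"
            )
        blocks = rng.choice(len(free_blocks), size=n_bg, p=weights)
        for b in blocks:
            chrom, lo, hi = free_blocks[int(b)]
            start = int(rng.integers(lo, hi - config.read_length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            sample_reads.append(
                GenomicInterval(chrom, start, start + config.read_length, strand))
        reads[sample] = sample_reads
    return reads


def _make_mirnas(config, rng):
    mirnas: Dict[str, str] = {}
    seen_cores = set()
    i = 0
    while len(mirnas) < config.n_mirnas:
        i += 1
        seq = "".join("ACGU"[b] for b in rng.integers(0, 4, size=config.mirna_length))
        core = seq[1:7]
        if core in seen_cores:
            continue
        seen_cores.add(core)
        mirnas[f"sim-miR-{i:03d}"] = seq
    return mirnas


def _mature_index_map(circ: CircRNA) -> List[Tuple[str, int]]:
    plus_order = [
        (f.interval.chrom, pos)
        for f in circ.exon_features
        for pos in range(f.interval.start, f.interval.end)
    ]
    if circ.span.strand == "-":
        return plus_order[::-1]
    return plus_order


def _mature_sequence(circ: CircRNA, genome_arr: Mapping[str, np.ndarray]) -> str:
    parts = [
        genome_arr[f.interval.chrom][f.interval.start : f.interval.end]
        .tobytes().decode("ascii")
        for f in circ.exon_features
    ]
    seq = "".join(parts)
    return revcomp(seq) if circ.span.strand == "-" else seq


def _write_mature(circ: CircRNA, new_seq: str, genome_arr: Dict[str, np.ndarray]) -> None:
    mapping = _mature_index_map(circ)
    if len(new_seq) != len(mapping):
        raise ValueError("edited sequence length differs from mature length")
    minus = circ.span.strand == "-"
    for i, base in enumerate(new_seq):
        chrom, pos = mapping[i]
        genome_arr[chrom][pos] = ord(complement(base)) if minus else ord(base)


def _make_junctions(circs, traj, rng):
    junctions = []
    for i, circ in enumerate(circs):
        support = int(rng.integers(2, 51)) if traj[i] is not None else int(rng.integers(1, 6))
        junctions.append(JunctionCall(circ.span, circ.circ_id, support))
    order = rng.permutation(len(junctions))
    return [junctions[int(k)] for k in order]


def _linear_tables(config, circs, class_of, traj, rpkm_pop, genes, rng):
    pops = list(config.populations)
    factor = {"U": config.up_factor, "D": config.down_factor, "F": 1.0}
    pair_circs = [
        c for i, c in enumerate(circs)
        if traj[i] is not None and class_of[i] in ("genic_exonic", "genic_other")
        and c.host_gene is not None
    ]
    rho = config.linear_correlation
    lin_log2: Dict[str, Dict[str, float]] = {}
    # host-gene linear abundance correlated with circ abundance per population
    for pop in pops:
        vals = np.array([
            math.log2(rpkm_pop[c.circ_id][pop] + 1e-3) for c in pair_circs
        ])
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        eps = rng.standard_normal(len(pair_circs))
        lin = 6.0 + 1.5 * (rho * z + math.sqrt(max(0.0, 1 - rho * rho)) * eps)
        for c, v in zip(pair_circs, lin):
            lin_log2.setdefault(c.host_gene, {})[pop] = float(v)
    gene_rows = {}
    for gene in genes:
        if gene.gene_id in lin_log2:
            gene_rows[gene.gene_id] = {
                pop: 2.0 ** lin_log2[gene.gene_id][pop] for pop in pops
            }
        else:
            base = 6.0 + 1.5 * rng.standard_normal()
            gene_rows[gene.gene_id] = {pop: 2.0 ** base for pop in pops}
    linear_rpkm = pd.DataFrame(gene_rows).T[pops]
    linear_rpkm.index.name = "gene_id"
    iso_rows = {}
    for gene in genes:
        txs = sorted(gene.transcripts)
        shares = [1.0] if len(txs) == 1 else [0.6, 0.4]
        for tx, share in zip(txs, shares):
            iso_rows[tx] = {
                pop: gene_rows[gene.gene_id][pop] * share for pop in pops
            }
    isoform_rpkm = pd.DataFrame(iso_rows).T[pops]
    isoform_rpkm.index.name = "transcript_id"
    # shared-exon fold changes: mostly concordant, a small planted fraction opposite
    traj_by_id = {circs[i].circ_id: traj[i] for i in range(len(circs))}
    movable = [c for c in pair_circs
               if traj_by_id[c.circ_id] not in (None, "FF")]
    n_opp = int(round(config.opposite_rate * len(pair_circs)))
    opposite_ids = {c.circ_id for c in movable[:n_opp]}
    invert = {"U": "D", "D": "U", "F": "F"}
    fc_rows = {}
    pair_truth: Dict[str, str] = {}
    for c in pair_circs:
        label = traj_by_id[c.circ_id]
        if c.circ_id in opposite_ids:
            exon_label = invert[label[0]] + invert[label[1]]
            pair_truth[c.circ_id] = "opposite"
        else:
            exon_label = label
            pair_truth[c.circ_id] = "mixed" if label == "FF" else "same"
        fc_rows[c.circ_id] = {
            "fc1": factor[exon_label[0]],
            "fc2": factor[exon_label[1]],
            "circ_fc1": factor[label[0]],
            "circ_fc2": factor[label[1]],
        }
    exon_fc = pd.DataFrame(fc_rows).T
    exon_fc.index.name = "circ_id"
    return linear_rpkm, isoform_rpkm, exon_fc, pair_truth
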