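"""Per-feature read counting, RPKM, expression calling and meta-features.

RPKM = count / (R * L) with R = library size x 1e-6 and L = feature length
x 1e-3. RPKM values are averaged across biological replicates within each
population; a feature is *expressed* when its per-population mean RPKM
strictly exceeds the threshold in at least one population. A circRNA is
expressed when at least one of its exon features is; intron features are
reported in the output table but excluded from sequences and downstream
statistics.
"""
from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .circ_annotate import CircRNA, Feature
from .io_formats import GenomicInterval

logger = logging.getLogger(__name__)

#: expression threshold (RPKM) derived from predicted-but-undetected introns
DEFAULT_RPKM_THRESHOLD = 3.5


def count_features(
    reads_by_sample: Mapping[str, Iterable[GenomicInterval]],
    features: Sequence[Feature],
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Count reads per feature per sample.

    A read increments a feature when they overlap by >= 1 bp on the same
    strand; a read overlapping several features increments each of them
    (no fractional assignment). Reads on chromosomes not covered by any
    feature are skipped and tallied in the returned summary.
    """
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for idx, feat in enumerate(features):
        key = (feat.interval.chrom, feat.interval.strand)
        trees.setdefault(key, IntervalTree()).addi(
            feat.interval.start, feat.interval.end, idx
        )
    known_chroms = {chrom for chrom, _ in trees}
    samples = list(reads_by_sample)
    counts = np.zeros((len(features), len(samples)), dtype=np.int64)
    skipped: Dict[str, int] = {}
    for j, sample in enumerate(samples):
        n_skipped = 0
        for read in reads_by_sample[sample]:
            if read.chrom not in known_chroms:
                n_skipped += 1
                continue
            tree = trees.get((read.chrom, read.strand))
            if tree is None:
                continue
            for hit in tree.overlap(read.start, read.end):
                counts[hit.data, j] += 1
        skipped[sample] = n_skipped
        if n_skipped:
            logger.info("sample %s: skipped %d reads on unknown chromosomes",
                        sample, n_skipped)
    df = pd.DataFrame(counts, index=[f.feature_id for f in features], columns=samples)
    return df, skipped


def rpkm(count: float, library_size: int, length_bp: int) -> float:
    """Reads per kilobase per million: count / ((library*1e-6)*(length*1e-3))."""
    if library_size <= 0:
        raise ValueError(f"library size must be positive, got {library_size}")
    if length_bp <= 0:
        raise ValueError(f"feature length must be positive, got {length_bp}")
    return count / ((library_size * 1e-6) * (length_bp * 1e-3))


def rpkm_matrix(
    counts: pd.DataFrame,
    library_sizes: Mapping[str, int],
    lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Vectorized RPKM over a feature x sample count matrix."""
    lib = np.array([library_sizes[s] for s in counts.columns], dtype=float)
    ln = np.array([lengths[f] for f in counts.index], dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    if (ln <= 0).any():
        raise ValueError("feature lengths must be positive")
    vals = counts.to_numpy(dtype=float) / ((lib[None, :] * 1e-6) * (ln[:, None] * 1e-3))
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def population_means(
    values: pd.DataFrame, design: Mapping[str, str], populations: Sequence[str]
) -> pd.DataFrame:
    """Arithmetic mean over each population's replicate columns."""
    out = {}
    for pop in populations:
        cols = [s for s in values.columns if design[s] == pop]
        if not cols:
            raise ValueError(f"population {pop!r} has no samples in the design")
        out[pop] = values[cols].mean(axis=1)
    return pd.DataFrame(out)


def derive_threshold(
    validated_circ_ids: Iterable[str],
    mean_rpkm: pd.DataFrame,
    features: Sequence[Feature],
) -> float:
    """Expression threshold from validated circRNAs' predicted introns.

    Returns the maximum over intron features of validated circRNAs of the
    maximum per-population mean RPKM: introns predicted but never detected
    bound the noise floor from above. When no validation set is available use
    :data:`DEFAULT_RPKM_THRESHOLD`.
    """
    validated = set(validated_circ_ids)
    if not validated:
        raise ValueError("validated set is empty; use DEFAULT_RPKM_THRESHOLD instead")
    intron_ids = [
        f.feature_id for f in features
        if f.kind == "intron" and f.circ_id in validated
    ]
    if not intron_ids:
        raise ValueError(
            "validated circRNAs contain no intron features; "
            "use DEFAULT_RPKM_THRESHOLD instead"
        )
    return float(mean_rpkm.loc[intron_ids].to_numpy().max())


def call_expressed(mean_rpkm: pd.DataFrame, threshold: float = DEFAULT_RPKM_THRESHOLD) -> Set[str]:
    """Features whose mean RPKM strictly exceeds the threshold in >= 1 population."""
    mask = (mean_rpkm > threshold).any(axis=1)
    return set(mean_rpkm.index[mask])


def define_circ_set(
    expressed_features: Set[str], features: Sequence[Feature]
) -> Set[str]:
    """CircRNAs with at least one *exon* feature expressed.

    An expressed intron alone never promotes its circRNA.
    """
    return {
        f.circ_id for f in features
        if f.kind == "exon" and f.feature_id in expressed_features
    }


def meta_feature_counts(
    counts: pd.DataFrame, circs: Sequence[CircRNA]
) -> pd.DataFrame:
    """Per-circRNA counts: sum of the circRNA's exon-feature counts."""
    rows = {}
    for circ in circs:
        ids = [f.feature_id for f in circ.exon_features if f.feature_id in counts.index]
        rows[circ.circ_id] = (
            counts.loc[ids].sum(axis=0) if ids
            else pd.Series(0, index=counts.columns)
        )
    return pd.DataFrame(rows).T.astype(np.int64)


def circ_rpkm(
    meta_counts: pd.DataFrame,
    library_sizes: Mapping[str, int],
    circs: Sequence[CircRNA],
) -> pd.DataFrame:
    """Circ-level RPKM with L = summed exon length (exon-only mature length)."""
    lengths = {c.circ_id: c.exonic_length for c in circs}
    return rpkm_matrix(meta_counts, library_sizes, lengths)
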