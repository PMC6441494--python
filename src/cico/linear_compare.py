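"""Circular-versus-linear host expression comparison.

Correlates circRNA and host mRNA abundance (Pearson on log2 RPKM), classifies
fold-change concordance between a circRNA and the shared exon of its linear
counterpart, and quantifies overlap with alternatively spliced genes. The
linear side is consumed as precomputed RPKM / fold-change tables.
"""
from __future__ import annotations

from typing import Dict, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .circ_annotate import CircRNA
from .diffexpr import DOWN_THRESHOLD, UP_THRESHOLD, _direction
from .expression import DEFAULT_RPKM_THRESHOLD
from .io_formats import Annotation

DEFAULT_LOG_PSEUDOCOUNT = 1e-3

CONCORDANCE_CLASSES = ("same", "opposite", "mixed")


def pearson_log(
    circ_rpkm: Sequence[float],
    linear_rpkm: Sequence[float],
    pseudocount: float = DEFAULT_LOG_PSEUDOCOUNT,
) -> Tuple[float, float]:
    """Pearson r and r^2 on log2(RPKM + pseudocount)."""
    a = np.log2(np.asarray(circ_rpkm, dtype=float) + pseudocount)
    b = np.log2(np.asarray(linear_rpkm, dtype=float) + pseudocount)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 points for a correlation")
    r = float(stats.pearsonr(a, b).statistic)
    return r, r * r


def exon_concordance(
    circ_fcs: Sequence[float],
    exon_fcs: Sequence[float],
    up: float = UP_THRESHOLD,
    down: float = DOWN_THRESHOLD,
) -> str:
    """Concordance of a circRNA's FC pattern with its shared linear exon.

    Per transition each FC is classed U/D/F. The pair is ``opposite`` when
    any transition runs in opposite directions (U vs D), ``same`` when no
    transition disagrees, at least one transition is concordantly non-flat
    and none is half-flat (one side moves, the other does not); everything
    else - including all-flat pairs - is ``mixed``.
    """
    if len(circ_fcs) != len(exon_fcs):
        raise ValueError("transition vectors must have equal length")
    n_agree = 0
    n_half = 0
    for fc_c, fc_e in zip(circ_fcs, exon_fcs):
        dc, de = _direction(fc_c, up, down), _direction(fc_e, up, down)
        if {dc, de} == {"U", "D"}:
            return "opposite"
        if dc == de and dc != "F":
            n_agree += 1
        elif dc != de:  # one flat, one not
            n_half += 1
    if n_agree >= 1 and n_half == 0:
        return "same"
    return "mixed"


def concordance_summary(
    pairs: Mapping[str, Tuple[Sequence[float], Sequence[float]]],
    up: float = UP_THRESHOLD,
    down: float = DOWN_THRESHOLD,
) -> pd.Series:
    """Counts of same/opposite/mixed over circ -> (circ FCs, exon FCs) pairs."""
    counts = {c: 0 for c in CONCORDANCE_CLASSES}
    for circ_fcs, exon_fcs in pairs.values():
        counts[exon_concordance(circ_fcs, exon_fcs, up=up, down=down)] += 1
    return pd.Series(counts)


def alt_splicing_overlap(
    annotation: Annotation,
    isoform_rpkm: pd.DataFrame,
    circs: Sequence[CircRNA],
    expressed_circ_ids: Set[str],
    threshold: float = DEFAULT_RPKM_THRESHOLD,
) -> Dict[str, object]:
    """Overlap of expressed circRNAs with alternatively spliced host genes.

    ``isoform_rpkm`` is indexed by transcript id with one column per
    population. An isoform is *expressed* when its RPKM exceeds the threshold
    in at least one population (same rule as for circRNAs). Reports:

    - genes with >= 2 expressed isoforms (and the total of expressed genes),
    - the fraction of expressed circRNAs hosted by such genes,
    - circRNAs sharing >= 1 identical exon with an isoform of such a gene
      that is expressed in all three populations.
    """
    tx_to_gene: Dict[str, str] = {}
    for gene in annotation.genes.values():
        for tx_id in gene.transcripts:
            tx_to_gene[tx_id] = gene.gene_id
    expressed_any = isoform_rpkm.index[(isoform_rpkm > threshold).any(axis=1)]
    expressed_all = set(isoform_rpkm.index[(isoform_rpkm > threshold).all(axis=1)])
    per_gene: Dict[str, int] = {}
    for tx_id in expressed_any:
        gene_id = tx_to_gene.get(tx_id)
        if gene_id is not None:
            per_gene[gene_id] = per_gene.get(gene_id, 0) + 1
    multi_genes = {g for g, n in per_gene.items() if n >= 2}
    hosted = [
        c for c in circs
        if c.circ_id in expressed_circ_ids and c.host_gene in multi_genes
    ]
    n_expressed = len([c for c in circs if c.circ_id in expressed_circ_ids])
    # circRNAs sharing an identical exon with an always-expressed isoform of
    # a differentially spliced gene
    n_shared_exon = 0
    for circ in hosted:
        gene = annotation.genes.get(circ.host_gene)
        if gene is None:
            continue
        circ_exons = {(f.interval.start, f.interval.end) for f in circ.exon_features}
        shared = False
        for tx_id, tx in gene.transcripts.items():
            if tx_id not in expressed_all:
                continue
            if circ_exons & set(tx.exons):
                shared = True
                break
        n_shared_exon += int(shared)
    return {
        "n_genes_expressed": len(per_gene),
        "n_genes_multi_isoform": len(multi_genes),
        "n_circs_expressed": n_expressed,
        "n_circs_in_multi_isoform_genes": len(hosted),
        "fraction_circs_in_multi_isoform_genes": (
            len(hosted) / n_expressed if n_expressed else 0.0
        ),
        "n_circs_sharing_exon_all_populations": n_shared_exon,
    }
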