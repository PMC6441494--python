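"""End-to-end pipeline: annotate -> quantify -> diffexp -> seeds -> orfcai
-> conserve -> compare-linear, driven by a single config with one root seed.

Every stage writes its table into the output directory and contributes its
input/output counts to ``run_manifest.json`` so the expression funnel
(putative -> expressed -> per-pattern) is auditable on any dataset.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import circ_annotate, conservation, diffexpr, expression, linear_compare, mirna_seeds, orf_cai
from .circ_annotate import CircRNA
from .io_formats import (
    Annotation,
    GenomicInterval,
    read_annotation,
    read_codon_usage,
    read_fasta,
    read_junction_calls,
    read_track,
    write_expressed_table,
)
from .synthetic_data import Bundle, SimConfig, generate_dataset

ALL_STAGES = (
    "annotate", "quantify", "diffexp", "seeds", "orfcai", "conserve",
    "compare_linear",
)

_STAGE_DEPS = {
    "quantify": ("annotate",),
    "diffexp": ("quantify",),
    "seeds": ("quantify",),
    "orfcai": ("quantify",),
    "conserve": ("quantify",),
    "compare_linear": ("quantify", "diffexp"),
}


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults are the pipeline's canonical operating point:
    expression RPKM > 3.5; FC >= 1.5 / <= 0.67; seed filters score >= 150
    and dG <= -19; ORFs >= 150 nt; eCAI at 95% confidence; 200-bp flanks.
    """

    out_dir: str = "cico_out"
    seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    # inputs: either a simulate block or explicit paths
    simulate: Optional[Dict[str, object]] = None
    junctions: Optional[str] = None
    gtf: Optional[str] = None
    genome: Optional[str] = None
    reads_dir: Optional[str] = None
    design: Optional[str] = None
    track: Optional[str] = None
    mirnas: Optional[str] = None
    codon_usage: Optional[str] = None
    linear_rpkm: Optional[str] = None
    isoform_rpkm: Optional[str] = None
    exon_fc: Optional[str] = None
    catalog: Optional[str] = None
    # thresholds
    rpkm_threshold: float = expression.DEFAULT_RPKM_THRESHOLD
    fc_up: float = diffexpr.UP_THRESHOLD
    fc_down: float = diffexpr.DOWN_THRESHOLD
    seed_min_score: float = mirna_seeds.DEFAULT_MIN_SCORE
    seed_max_dg: float = mirna_seeds.DEFAULT_MAX_DG
    linear_scan: bool = False
    orf_min_len: int = orf_cai.DEFAULT_MIN_ORF_LEN
    ecai_confidence: float = orf_cai.DEFAULT_CONFIDENCE
    ecai_n_null: int = orf_cai.DEFAULT_N_NULL
    flank: int = conservation.DEFAULT_FLANK
    id_prefix: str = "CiCo_sim_circ"
    populations: Sequence[str] = ("PP", "DP", "N")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seed(root: int, k: int) -> int:
    return (root * 1_000_003 + 7919 * (k + 1)) % (2**31 - 1)


def _read_reads_bed(path) -> List[GenomicInterval]:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return [
        GenomicInterval(c, int(s), int(e), st)
        for c, s, e, st in zip(df.chrom, df.start, df.end, df.strand)
    ]


def _load_inputs(config: PipelineConfig) -> Dict[str, object]:
    """Materialize all inputs, simulating them first when requested."""
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_seed = int(sim_kwargs.pop("seed", config.seed))
        sim = SimConfig(**sim_kwargs)
        bundle = generate_dataset(sim, seed=sim_seed)
        indir = os.path.join(config.out_dir, "inputs")
        bundle.write(indir)
        config.junctions = os.path.join(indir, "junctions.bed")
        config.gtf = os.path.join(indir, "annotation.gtf")
        config.genome = os.path.join(indir, "genome.fa")
        config.reads_dir = os.path.join(indir, "reads")
        config.design = os.path.join(indir, "design.tsv")
        config.track = os.path.join(indir, "phylop.bedgraph")
        config.mirnas = os.path.join(indir, "mirnas.fa")
        config.codon_usage = os.path.join(indir, "codon_usage.tsv")
        config.linear_rpkm = os.path.join(indir, "linear_rpkm.tsv")
        config.isoform_rpkm = os.path.join(indir, "isoform_rpkm.tsv")
        config.exon_fc = os.path.join(indir, "exon_fc.tsv")
        config.id_prefix = sim.id_prefix
        config.populations = sim.populations
    needs_reads = "quantify" in config.stages
    required = ["junctions", "gtf", "genome"] + (["design"] if needs_reads else [])
    for key in required:
        path = getattr(config, key)
        if path is None or not os.path.exists(path):
            raise FileNotFoundError(f"required input {key!r} missing: {path}")
    inputs: Dict[str, object] = {}
    inputs["genome"] = read_fasta(config.genome)
    chrom_sizes = {c: len(s) for c, s in inputs["genome"].items()}
    inputs["chrom_sizes"] = chrom_sizes
    inputs["annotation"] = read_annotation(config.gtf, chrom_sizes=chrom_sizes)
    inputs["junctions"] = read_junction_calls(config.junctions)
    if needs_reads:
        design_df = pd.read_csv(config.design, sep="\t")
        inputs["design"] = dict(zip(design_df["sample"], design_df["population"]))
        reads = {}
        for sample in inputs["design"]:
            path = os.path.join(config.reads_dir, f"{sample}.bed")
            if not os.path.exists(path):
                raise FileNotFoundError(f"reads for sample {sample} missing: {path}")
            reads[sample] = _read_reads_bed(path)
        inputs["reads"] = reads
    if config.track and os.path.exists(config.track):
        inputs["track"] = read_track(config.track)
    if config.mirnas and os.path.exists(config.mirnas):
        inputs["mirnas"] = read_fasta(config.mirnas)
    if config.codon_usage and os.path.exists(config.codon_usage):
        inputs["codon_usage"] = read_codon_usage(config.codon_usage)
    for key in ("linear_rpkm", "isoform_rpkm", "exon_fc"):
        path = getattr(config, key)
        if path and os.path.exists(path):
            inputs[key] = pd.read_csv(path, sep="\t", index_col=0)
    if config.catalog and os.path.exists(config.catalog):
        inputs["catalog"] = read_junction_calls(config.catalog)
    return inputs


def run_all(config: PipelineConfig) -> Dict[str, object]:
    """Run the enabled stages in order; returns in-memory results and writes
    per-stage tables plus ``run_manifest.json`` under ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    stages = list(config.stages)
    for stage in stages:
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in stages:
                raise RuntimeError(f"stage {stage!r} requires stage {dep!r}")
    inputs = _load_inputs(config)
    manifest: Dict[str, object] = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
    }
    results: Dict[str, object] = {"inputs": inputs, "config": config}
    stage_counts: Dict[str, Dict[str, object]] = manifest["stages"]

    circs: List[CircRNA] = []
    if "annotate" in stages:
        circs = circ_annotate.annotate_junctions(
            inputs["junctions"], inputs["annotation"], genome=inputs["genome"],
            prefix=config.id_prefix,
        )
        hits = None
        if "catalog" in inputs:
            hits = circ_annotate.catalog_overlap(
                circs, [j.interval for j in inputs["catalog"]],
                catalog_names=[j.name for j in inputs["catalog"]],
            )
        class_counts: Dict[str, int] = {c: 0 for c in circ_annotate.CIRC_CLASSES}
        for c in circs:
            class_counts[c.circ_class] += 1
        stage_counts["annotate"] = {
            "n_junctions": len(inputs["junctions"]),
            "n_circs": len(circs),
            "class_counts": class_counts,
        }
        results["circs"] = circs
        results["catalog_hits"] = hits
        _write_circ_table(circs, hits, os.path.join(config.out_dir, "circs.tsv"))

    if "quantify" in stages:
        features = [f for c in circs for f in c.features]
        counts, skipped = expression.count_features(inputs["reads"], features)
        library_sizes = {s: len(r) for s, r in inputs["reads"].items()}
        lengths = {f.feature_id: f.interval.length for f in features}
        rpkm = expression.rpkm_matrix(counts, library_sizes, lengths)
        mean_rpkm = expression.population_means(
            rpkm, inputs["design"], config.populations)
        expressed_features = expression.call_expressed(mean_rpkm, config.rpkm_threshold)
        expressed_circs = expression.define_circ_set(expressed_features, features)
        meta_counts = expression.meta_feature_counts(counts, circs)
        stage_counts["quantify"] = {
            "n_features": len(features),
            "n_expressed_features": len(expressed_features),
            "n_expressed_circs": len(expressed_circs),
            "rpkm_threshold": config.rpkm_threshold,
            "skipped_reads": skipped,
        }
        results.update(
            counts=counts, rpkm=rpkm, mean_rpkm=mean_rpkm,
            expressed_features=expressed_features, expressed_circs=expressed_circs,
            meta_counts=meta_counts, library_sizes=library_sizes,
        )
        _write_expression_tables(config, circs, mean_rpkm, expressed_features,
                                 results.get("catalog_hits"))

    if "diffexp" in stages:
        expressed = sorted(results["expressed_circs"])
        calls = diffexpr.trajectory_calls(
            results["meta_counts"].loc[expressed], inputs["design"],
            populations=tuple(config.populations),
            up=config.fc_up, down=config.fc_down,
        )
        summary = diffexpr.pattern_summary(list(calls["label"]))
        stage_counts["diffexp"] = {"n_circs": len(calls), "labels": summary}
        results["trajectories"] = calls
        calls.to_csv(os.path.join(config.out_dir, "trajectories.tsv"), sep="\t")

    sequences: Dict[str, str] = {}
    if {"seeds", "orfcai"} & set(stages):
        sequences = {
            c.circ_id: c.sequence for c in circs
            if c.circ_id in results["expressed_circs"] and c.sequence
        }

    if "seeds" in stages:
        matches = mirna_seeds.scan_all(
            sequences, inputs["mirnas"],
            circular=not config.linear_scan, compute_scores=True,
        )
        summaries = mirna_seeds.filter_and_count(
            matches, min_score=config.seed_min_score, max_dg=config.seed_max_dg)
        stage_counts["seeds"] = {
            "n_sites": len(matches),
            "n_sites_after_filter": sum(s.total for s in summaries),
            "n_circs_with_sites": len(summaries),
        }
        results["seed_matches"] = matches
        results["seed_summaries"] = summaries
        _write_seed_tables(config, matches, summaries, sequences)

    if "orfcai" in stages:
        stage_counts["orfcai"], orf_results = _run_orfcai(
            config, inputs, sequences)
        results.update(orf_results)

    if "conserve" in stages and "track" in inputs:
        expressed_circs = [c for c in circs if c.circ_id in results["expressed_circs"]]
        cons = conservation.conservation_analysis(
            expressed_circs, inputs["track"], inputs["annotation"],
            inputs["chrom_sizes"], flank=config.flank,
            seed=_stage_seed(config.seed, 5),
        )
        stage_counts["conserve"] = {
            r.group: {"real_mean": r.real_mean, "shuffled_mean": r.shuffled_mean,
                      "t": r.t, "p": r.p, "n": len(r.real_means)}
            for r in cons
        }
        results["conservation"] = cons
        pd.DataFrame(stage_counts["conserve"]).T.to_csv(
            os.path.join(config.out_dir, "conservation.tsv"), sep="\t")

    if "compare_linear" in stages and "linear_rpkm" in inputs:
        stage_counts["compare_linear"], lin_results = _run_compare_linear(
            config, inputs, results, circs)
        results.update(lin_results)

    with open(os.path.join(config.out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    results["run_manifest"] = manifest
    return results


def _write_circ_table(circs, hits, path) -> None:
    rows = []
    for c in circs:
        hit = hits.get(c.circ_id) if hits else None
        rows.append({
            "chrom": c.span.chrom, "start": c.span.start, "end": c.span.end,
            "name": c.circ_id, "score": c.support, "strand": c.span.strand,
            "class": c.circ_class, "host_gene": c.host_gene or "Intergenic",
            "n_exons": len(c.exon_features) if c.circ_class == "genic_exonic" else "",
            "catalog_id": hit.catalog_name if hit and hit.known else "",
            "overlap_level": hit.level if hit and hit.level is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_expression_tables(config, circs, mean_rpkm, expressed_features, hits):
    rows = []
    for c in circs:
        hit = hits.get(c.circ_id) if hits else None
        for f in c.features:
            if f.feature_id not in expressed_features:
                continue
            row = {
                "chrom": f.interval.chrom, "start": f.interval.start,
                "end": f.interval.end, "name": f.feature_id,
                "score": 0, "strand": f.interval.strand,
                "circ_id": c.circ_id,
                "gene_name": c.host_gene if c.host_gene else "Intergenic",
                "gene_id": c.host_gene or "",
                "exon_count": (
                    str(len(c.exon_features)) if c.circ_class == "genic_exonic" else ""
                ),
                "catalog_id": hit.catalog_name if hit and hit.known else "",
                "overlap_level": hit.level if hit and hit.level is not None else "",
            }
            for pop in mean_rpkm.columns:
                row[f"rpkm_{pop}"] = mean_rpkm.at[f.feature_id, pop]
            rows.append(row)
    write_expressed_table(rows, os.path.join(config.out_dir, "expressed_features.tsv"))


def _write_seed_tables(config, matches, summaries, sequences) -> None:
    match_df = pd.DataFrame([
        {"circ_id": m.circ_id, "mirna": m.mirna_id, "start": m.start,
         "category": m.category, "score": m.score, "energy": m.energy,
         "circ_length": len(sequences[m.circ_id])}
        for m in matches
    ])
    match_df.to_csv(os.path.join(config.out_dir, "seeds.tsv"), sep="\t", index=False)
    rows = []
    for s in summaries:
        for mirna, n in sorted(s.per_mirna.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append({"circ_id": s.circ_id, "mirna": mirna, "n_seeds": n,
                         "max_single": s.max_single, "n_distinct": s.n_distinct})
    pd.DataFrame(rows).to_csv(
        os.path.join(config.out_dir, "seed_summary.tsv"), sep="\t", index=False)


def _transcript_sequences(annotation: Annotation, genome) -> List[str]:
    from ._seq import revcomp
    seqs = []
    for gene in annotation.genes.values():
        chrom = genome[gene.chrom]
        for tx in gene.transcripts.values():
            s = "".join(chrom[a:b] for a, b in tx.exons)
            seqs.append(revcomp(s) if gene.strand == "-" else s)
    return seqs


def _run_orfcai(config: PipelineConfig, inputs, sequences):
    usage = inputs["codon_usage"]
    w = orf_cai.relative_adaptiveness(usage)
    circ_orfs = []
    for circ_id, seq in sorted(sequences.items()):
        for rec in orf_cai.find_orfs(seq, min_len=config.orf_min_len, circ_id=circ_id):
            rec.cai = orf_cai.cai(rec.sequence[: rec.length // 3 * 3], w)
            circ_orfs.append(rec)
    pool = [o.sequence for o in circ_orfs]
    threshold = None
    if pool:
        threshold = orf_cai.ecai(
            pool, w, n_null=config.ecai_n_null,
            confidence=config.ecai_confidence,
            seed=_stage_seed(config.seed, 4),
        )
        for o in circ_orfs:
            o.above_expected = o.cai > threshold
    lengths = [len(s) for s in sequences.values()]
    transcripts = _transcript_sequences(inputs["annotation"], inputs["genome"])
    genomic, transcriptomic = orf_cai.shuffled_controls(
        inputs["genome"], transcripts, lengths, seed=_stage_seed(config.seed, 14))
    control_stats = {}
    chi2_stats = {}
    n_above = sum(1 for o in circ_orfs if o.above_expected)
    for name, control in (("genomic", genomic), ("transcriptomic", transcriptomic)):
        orfs = []
        for seq in control:
            for rec in orf_cai.find_orfs(seq, min_len=config.orf_min_len):
                rec.cai = orf_cai.cai(rec.sequence[: rec.length // 3 * 3], w)
                orfs.append(rec)
        above = sum(1 for o in orfs if threshold is not None and o.cai > threshold)
        control_stats[name] = {"n_orfs": len(orfs), "n_above": above}
        if circ_orfs and orfs:
            stat, p = orf_cai.chi2_2x2(
                n_above, len(circ_orfs) - n_above, above, len(orfs) - above)
            chi2_stats[name] = {"chi2": stat, "p": p}
    counts = {
        "n_sequences": len(sequences),
        "n_orfs": len(circ_orfs),
        "n_above_ecai": n_above,
        "ecai": threshold,
        "controls": control_stats,
        "chi2": chi2_stats,
    }
    orf_df = pd.DataFrame([
        {"circ_id": o.circ_id, "start": o.start, "end": o.end,
         "length": o.length, "has_stop": o.has_stop, "cai": o.cai,
         "above_expected": o.above_expected}
        for o in circ_orfs
    ])
    orf_df.to_csv(os.path.join(config.out_dir, "orfs.tsv"), sep="\t", index=False)
    with open(os.path.join(config.out_dir, "orf_summary.json"), "w") as fh:
        json.dump(counts, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return counts, {"orfs": circ_orfs, "ecai": threshold, "orf_chi2": chi2_stats}


def _run_compare_linear(config: PipelineConfig, inputs, results, circs):
    linear = inputs["linear_rpkm"]
    meta_counts = results["meta_counts"]
    library_sizes = results["library_sizes"]
    expressed = results["expressed_circs"]
    by_id = {c.circ_id: c for c in circs}
    pair_circs = [
        by_id[cid] for cid in sorted(expressed)
        if by_id[cid].host_gene in linear.index
    ]
    crpkm = expression.circ_rpkm(
        meta_counts.loc[[c.circ_id for c in pair_circs]], library_sizes, pair_circs)
    circ_means = expression.population_means(
        crpkm, inputs["design"], config.populations)
    pearson = {}
    for pop in config.populations:
        x = circ_means[pop].to_numpy()
        y = linear.loc[[c.host_gene for c in pair_circs], pop].to_numpy()
        if len(x) >= 3:
            r, r2 = linear_compare.pearson_log(x, y)
            pearson[pop] = {"r": r, "r2": r2}
    concordance = {}
    if "exon_fc" in inputs:
        fc = inputs["exon_fc"]
        pairs = {
            cid: ((row["circ_fc1"], row["circ_fc2"]), (row["fc1"], row["fc2"]))
            for cid, row in fc.iterrows() if cid in expressed
        }
        concordance = linear_compare.concordance_summary(
            pairs, up=config.fc_up, down=config.fc_down).to_dict()
    alt = {}
    if "isoform_rpkm" in inputs:
        alt = linear_compare.alt_splicing_overlap(
            inputs["annotation"], inputs["isoform_rpkm"], circs, expressed,
            threshold=config.rpkm_threshold)
    counts = {"pearson": pearson, "concordance": concordance, "alt_splicing": alt}
    with open(os.path.join(config.out_dir, "linear_compare.json"), "w") as fh:
        json.dump(counts, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return counts, {"pearson": pearson, "concordance": concordance,
                    "alt_splicing": alt}
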