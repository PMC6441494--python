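"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates are held 0-based half-open (BED convention) internally.
Readers convert at the boundary: BED-like inputs are taken as 0-based
half-open, GTF as 1-based inclusive. Writers convert back, so a
read -> write -> read round trip is the identity.

Parsing is total: every malformed line is reported with its line number.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

STRANDS = frozenset({"+", "-", "."})

#: Sense codons grouped by amino acid (standard genetic code, DNA alphabet).
SYNONYMOUS_FAMILIES: Dict[str, Tuple[str, ...]] = {
    "F": ("TTT", "TTC"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "I": ("ATT", "ATC", "ATA"),
    "M": ("ATG",),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "Y": ("TAT", "TAC"),
    "H": ("CAT", "CAC"),
    "Q": ("CAA", "CAG"),
    "N": ("AAT", "AAC"),
    "K": ("AAA", "AAG"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "C": ("TGT", "TGC"),
    "W": ("TGG",),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
}
SENSE_CODONS: Tuple[str, ...] = tuple(
    c for fam in SYNONYMOUS_FAMILIES.values() for c in fam
)
CODON_TO_AA: Dict[str, str] = {
    c: aa for aa, fam in SYNONYMOUS_FAMILIES.items() for c in fam
}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class JunctionCall:
    """One backsplice-junction prediction (find_circ-style BED6 record)."""

    interval: GenomicInterval
    name: str
    support: int
    extra: Tuple[str, ...] = ()


def read_junction_calls(path) -> List[JunctionCall]:
    """Read BED6-like junction records; no read-support filter is applied.

    Columns beyond the first six are preserved opaquely in ``extra``.
    """
    calls: List[JunctionCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"line {lineno}: expected >= 6 columns, got {len(parts)}")
            chrom, start_s, end_s, name, score_s, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            try:
                support = int(float(score_s))
            except ValueError:
                support = 0
            calls.append(JunctionCall(iv, name, support, tuple(parts[6:])))
    return calls


def write_junction_calls(calls: Sequence[JunctionCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            cols = [iv.chrom, str(iv.start), str(iv.end), c.name, str(c.support), iv.strand]
            cols.extend(c.extra)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation (GTF)
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    exons: List[Tuple[int, int]] = field(default_factory=list)  # 0-based half-open


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    name: str = ""
    transcripts: Dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> Tuple[int, int]:
        starts = [e[0] for t in self.transcripts.values() for e in t.exons]
        ends = [e[1] for t in self.transcripts.values() for e in t.exons]
        return min(starts), max(ends)

    def exon_union(self) -> List[Tuple[int, int]]:
        """Union of exon intervals across all transcripts, merged into
        non-overlapping blocks sorted by genomic start."""
        exons = sorted(
            e for t in self.transcripts.values() for e in t.exons
        )
        merged: List[Tuple[int, int]] = []
        for s, e in exons:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def intron_blocks(self) -> List[Tuple[int, int]]:
        blocks = self.exon_union()
        return [(blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)]


class Annotation:
    """Gene models (gene -> transcripts -> ordered exons) with a spatial index."""

    def __init__(self, genes: Mapping[str, Gene]):
        self.genes: Dict[str, Gene] = dict(genes)
        self._trees: Dict[str, IntervalTree] = {}
        for g in self.genes.values():
            s, e = g.span
            self._trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._trees)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> List[Gene]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self.genes[g] for g in hits]

    def exonic_blocks(self) -> Dict[str, List[Tuple[int, int]]]:
        """Merged exon blocks per chromosome over all genes."""
        per_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for g in self.genes.values():
            per_chrom.setdefault(g.chrom, []).extend(g.exon_union())
        return {c: _merge_blocks(bs) for c, bs in per_chrom.items()}

    def intronic_blocks(self) -> Dict[str, List[Tuple[int, int]]]:
        per_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for g in self.genes.values():
            per_chrom.setdefault(g.chrom, []).extend(g.intron_blocks())
        return {c: _merge_blocks(bs) for c, bs in per_chrom.items() if bs}


def _merge_blocks(blocks: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation(path, chrom_sizes: Optional[Mapping[str, int]] = None) -> Annotation:
    """Read exon records from a GTF-like file into gene models.

    GTF coordinates are 1-based inclusive and are converted to 0-based
    half-open on entry. Exons of each transcript are sorted by genomic start.
    """
    genes: Dict[str, Gene] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"line {lineno}: expected 9 GTF columns")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = parts[:9]
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if start < 0 or start >= end:
                raise ValueError(f"line {lineno}: invalid exon coordinates {start1}-{end1}")
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise ValueError(
                        f"line {lineno}: exon end {end} beyond chromosome "
                        f"{chrom} length {chrom_sizes[chrom]}"
                    )
            if strand not in ("+", "-"):
                raise ValueError(f"line {lineno}: exon strand must be + or -")
            attr = dict(_GTF_ATTR.findall(attrs))
            gene_id = attr.get("gene_id")
            tx_id = attr.get("transcript_id")
            if not gene_id or not tx_id:
                raise ValueError(f"line {lineno}: missing gene_id/transcript_id")
            gene = genes.get(gene_id)
            if gene is None:
                gene = Gene(gene_id, chrom, strand, name=attr.get("gene_name", gene_id))
                genes[gene_id] = gene
            if gene.strand != strand:
                raise ValueError(
                    f"line {lineno}: gene {gene_id} mixes strands "
                    f"({gene.strand} vs {strand})"
                )
            if gene.chrom != chrom:
                raise ValueError(f"line {lineno}: gene {gene_id} spans chromosomes")
            tx = gene.transcripts.setdefault(tx_id, Transcript(tx_id))
            tx.exons.append((start, end))
    for gene in genes.values():
        for tx in gene.transcripts.values():
            tx.exons.sort()
    return Annotation(genes)


def write_annotation(annotation: Annotation, path) -> None:
    """Write exon records as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in sorted(annotation.genes.values(), key=lambda g: (g.chrom, g.span)):
            for tx in sorted(gene.transcripts.values(), key=lambda t: t.transcript_id):
                for s, e in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'gene_name "{gene.name}";'
                    )
                    fh.write(
                        "\t".join(
                            [gene.chrom, "cico", "exon", str(s + 1), str(e),
                             ".", gene.strand, ".", attrs]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Conservation track
# ---------------------------------------------------------------------------

class ConservationTrack:
    """Per-base conservation scores (phyloP-like) with an explicit missing mask.

    Scores are held as dense per-chromosome arrays over the covered span so
    that averaging can distinguish score 0 from no score.
    """

    def __init__(self) -> None:
        # chrom -> (offset, scores float64[], covered bool[])
        self._data: Dict[str, Tuple[int, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_dense(
        cls,
        scores: Mapping[str, np.ndarray],
        masks: Optional[Mapping[str, np.ndarray]] = None,
    ) -> "ConservationTrack":
        track = cls()
        for chrom, arr in scores.items():
            arr = np.asarray(arr, dtype=float)
            mask = (
                np.asarray(masks[chrom], dtype=bool)
                if masks is not None and chrom in masks
                else np.ones(arr.shape, dtype=bool)
            )
            track._data[chrom] = (0, arr, mask)
        return track

    @classmethod
    def from_intervals(
        cls, records: Iterable[Tuple[str, int, int, float]]
    ) -> "ConservationTrack":
        per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if not np.isfinite(value):
                raise ValueError(f"non-finite score at {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping bedGraph intervals on {chrom} at {s2} < {e1}"
                    )
            offset = ivs[0][0]
            length = ivs[-1][1] - offset
            scores = np.zeros(length)
            covered = np.zeros(length, dtype=bool)
            for s, e, v in ivs:
                scores[s - offset : e - offset] = v
                covered[s - offset : e - offset] = True
            track._data[chrom] = (offset, scores, covered)
        return track

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._data)

    def values(self, chrom: str, start: int, end: int) -> Tuple[np.ndarray, np.ndarray]:
        """(scores, covered) for the requested span; uncovered outside data."""
        n = end - start
        if chrom not in self._data:
            return np.zeros(n), np.zeros(n, dtype=bool)
        offset, scores, covered = self._data[chrom]
        out = np.zeros(n)
        mask = np.zeros(n, dtype=bool)
        lo = max(start, offset)
        hi = min(end, offset + len(scores))
        if lo < hi:
            out[lo - start : hi - start] = scores[lo - offset : hi - offset]
            mask[lo - start : hi - start] = covered[lo - offset : hi - offset]
        return out, mask

    def mean(self, chrom: str, start: int, end: int) -> Tuple[float, int]:
        """(mean over covered bases, number of covered bases); mean is NaN
        when no base in the span carries a score."""
        scores, mask = self.values(chrom, start, end)
        n = int(mask.sum())
        if n == 0:
            return float("nan"), 0
        return float(scores[mask].mean()), n

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chromosomes:
                offset, scores, covered = self._data[chrom]
                # run-length encode consecutive equal covered scores
                idx = np.flatnonzero(covered)
                if idx.size == 0:
                    continue
                breaks = np.flatnonzero(
                    (np.diff(idx) != 1) | (np.diff(scores[idx]) != 0)
                )
                starts = np.concatenate([[0], breaks + 1])
                ends = np.concatenate([breaks, [idx.size - 1]])
                rows = [
                    f"{chrom}\t{offset + idx[a]}\t{offset + idx[b] + 1}\t{scores[idx[a]]:.6g}"
                    for a, b in zip(starts, ends)
                ]
                fh.write("\n".join(rows) + "\n")


def read_track(path) -> ConservationTrack:
    """Read a bedGraph-like file into a :class:`ConservationTrack`."""
    records: List[Tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"line {lineno}: expected 4 bedGraph columns")
            chrom, start_s, end_s, value_s = parts[:4]
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed bedGraph record") from exc
            if start < 0 or start >= end:
                raise ValueError(f"line {lineno}: invalid interval {start}-{end}")
            records.append((chrom, start, end, value))
    return ConservationTrack.from_intervals(records)


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Codon usage frequencies per thousand codons.

    All 61 sense codons must be present with non-negative frequency, and each
    synonymous family must contain at least one codon with positive usage.
    """

    freqs: Dict[str, float]

    def __post_init__(self) -> None:
        freqs = {c.upper().replace("U", "T"): float(v) for c, v in self.freqs.items()}
        missing = [c for c in SENSE_CODONS if c not in freqs]
        if missing:
            raise ValueError(f"codon usage table missing sense codons: {missing[:5]}...")
        for c, v in freqs.items():
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"codon {c}: invalid frequency {v}")
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            if all(freqs[c] == 0 for c in fam):
                raise ValueError(f"amino acid {aa}: all synonymous codons have zero usage")
        self.freqs = freqs

    def __getitem__(self, codon: str) -> float:
        return self.freqs[codon.upper().replace("U", "T")]


def read_codon_usage(path) -> CodonUsageTable:
    """Read a two-column TSV (codon, frequency per thousand)."""
    freqs: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected codon and frequency")
            try:
                freqs[parts[0]] = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric frequency") from exc
    return CodonUsageTable(freqs)


def write_codon_usage(table: CodonUsageTable, path) -> None:
    with open(path, "w") as fh:
        for codon in sorted(table.freqs):
            fh.write(f"{codon}\t{table.freqs[codon]:.4f}\n")


# ---------------------------------------------------------------------------
# FASTA and tables
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)


EXPRESSED_TABLE_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "circ_id", "gene_name", "gene_id", "exon_count", "catalog_id", "overlap_level",
]


def write_expressed_table(rows: Iterable[Mapping[str, object]], path) -> None:
    """Write the per-feature expressed table.

    The first six columns are BED; then circ id, overlapped gene name (or the
    literal ``Intergenic``), gene id, exon count (empty unless the circRNA is
    genic-exonic), catalog id (empty if novel) and the overlap level.
    """
    df = pd.DataFrame(list(rows))
    for col in EXPRESSED_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[EXPRESSED_TABLE_COLUMNS + [c for c in df.columns if c not in EXPRESSED_TABLE_COLUMNS]]
    df.to_csv(path, sep="\t", index=False)


def read_expressed_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"exon_count": "string", "catalog_id": "string"})
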