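"""miRNA seed-site scanning on mature circRNA sequences.

A site is any target hexamer Watson-Crick complementary to miRNA positions
2-7 (the 6mer core). The category is upgraded to 7mer-m8 when the target
also pairs position 8, to 7mer-A1 when an A faces position 1, and to 8mer
when both hold. Because the substrate is circular, the scan by default
extends the sequence by its first (miRNA length - 1) bases so that
junction-spanning sites are found once, at their modular position.

Each site carries a local-complementarity alignment score (match +5, G:U
wobble +1, mismatch -3, gap open -8, gap extend -2) and a duplex free energy
from a nearest-neighbor stacking sum over Watson-Crick stacks (Turner-style
RNA parameters, kcal/mol at 37C). These are pass/fail gates for the
downstream site filters, not a reimplementation of any specific aligner's
scoring.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import as_rna, complement, revcomp

SEED_CATEGORIES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

DEFAULT_MIN_SCORE = 150.0
DEFAULT_MAX_DG = -19.0

MATCH_SCORE = 5.0
WOBBLE_SCORE = 1.0
MISMATCH_SCORE = -3.0
GAP_OPEN = -8.0
GAP_EXTEND = -2.0

#: Watson-Crick nearest-neighbor stack free energies, keyed by the target
#: 5'->3' dinucleotide (the paired strand follows by complementarity).
STACK_DG = {
    "AA": -0.93, "UU": -0.93, "AU": -1.10, "UA": -1.33,
    "CU": -2.08, "AG": -2.08, "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24, "GA": -2.35, "UC": -2.35,
    "CG": -2.36, "GG": -3.26, "CC": -3.26, "GC": -3.42,
}
HELIX_INIT_DG = 4.09
TERMINAL_AU_DG = 0.45


@dataclass
class SeedMatch:
    circ_id: str
    mirna_id: str
    start: int  # 0-based start of the 6mer core on the mature sequence
    category: str
    score: Optional[float] = None
    energy: Optional[float] = None


@dataclass
class SeedSummary:
    circ_id: str
    per_mirna: Dict[str, int] = field(default_factory=dict)

    @property
    def max_single(self) -> int:
        return max(self.per_mirna.values(), default=0)

    @property
    def n_distinct(self) -> int:
        return len(self.per_mirna)

    @property
    def total(self) -> int:
        return sum(self.per_mirna.values())


def scan(
    sequence: str,
    mirna: str,
    circular: bool = True,
    circ_id: str = "",
    mirna_id: str = "",
) -> List[SeedMatch]:
    """Find all seed sites of one miRNA on one mature sequence.

    Returns matches with their Bartel category; rotation of a circular
    sequence changes only the reported positions, never the category
    multiset.
    """
    s = as_rna(sequence)
    m = as_rna(mirna)
    if len(m) < 8:
        raise ValueError(f"miRNA {mirna_id or mirna!r} shorter than 8 nt")
    n = len(s)
    if n < 6:
        return []
    core = revcomp(m[1:7], rna=True)  # pairs miRNA positions 2-7
    m8_partner = complement(m[7], rna=True)
    ext = s + s[: min(len(m) - 1, n)] if circular else s
    matches: List[SeedMatch] = []
    pos = ext.find(core)
    while pos != -1:
        if pos >= n:
            break
        if circular:
            prev: Optional[str] = s[(pos - 1) % n]
            nxt: Optional[str] = ext[pos + 6] if pos + 6 < len(ext) else s[(pos + 6) % n]
        else:
            prev = s[pos - 1] if pos >= 1 else None
            nxt = s[pos + 6] if pos + 6 < n else None
        has_m8 = prev == m8_partner
        has_a1 = nxt == "A"
        if has_m8 and has_a1:
            category = "8mer"
        elif has_m8:
            category = "7mer-m8"
        elif has_a1:
            category = "7mer-A1"
        else:
            category = "6mer"
        matches.append(SeedMatch(circ_id, mirna_id, pos, category))
        pos = ext.find(core, pos + 1)
    return matches


def _aligner() -> Align.PairwiseAligner:
    alphabet = "ACGUN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                matrix[a, b] = 0.0
            elif a == b:
                matrix[a, b] = MATCH_SCORE
            elif (a, b) in (("G", "A"), ("U", "C")):
                # target base vs complement-of-miRNA base: G:U wobbles
                matrix[a, b] = WOBBLE_SCORE
            else:
                matrix[a, b] = MISMATCH_SCORE
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _aligner()


def _site_context(sequence: str, match: SeedMatch, mirna: str, circular: bool) -> str:
    """Window of +/- one miRNA length around the 6mer core, wrapping if circular."""
    s = as_rna(sequence)
    m = len(as_rna(mirna))
    n = len(s)
    lo, hi = match.start - m, match.start + 6 + m
    if circular:
        pad = m // n + 1  # enough copies on each side even for short circles
        rep = s * (2 * pad + 1)
        return rep[lo + pad * n : hi + pad * n]
    return s[max(0, lo) : min(n, hi)]


def _align_site(context: str, mirna: str):
    rcm = revcomp(as_rna(mirna), rna=True)
    alignments = _ALIGNER.align(context, rcm)
    try:
        return alignments[0], rcm
    except IndexError:
        return None, rcm


def site_score(sequence: str, match: SeedMatch, mirna: str, circular: bool = True) -> float:
    """Local complementarity alignment score of the site context vs the miRNA."""
    context = _site_context(sequence, match, mirna, circular)
    alignment, _ = _align_site(context, mirna)
    return float(alignment.score) if alignment is not None else 0.0


def site_energy(sequence: str, match: SeedMatch, mirna: str, circular: bool = True) -> float:
    """Duplex free energy (kcal/mol): helix initiation plus the sum of
    Watson-Crick nearest-neighbor stacks in the best local alignment, with a
    terminal penalty for closing A:U pairs. Wobble-paired columns interrupt
    the stack sum. Always finite; 0.0 when nothing pairs."""
    context = _site_context(sequence, match, mirna, circular)
    alignment, rcm = _align_site(context, mirna)
    if alignment is None:
        return 0.0
    target_blocks, query_blocks = alignment.aligned
    paired: List[Tuple[int, str]] = []  # (target position, target base) of WC pairs
    dg = 0.0
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        for k in range(te - ts):
            t = context[ts + k]
            q = rcm[qs + k]
            if t == q:  # complement-of-miRNA equals target <=> Watson-Crick
                paired.append((ts + k, t))
    if not paired:
        return 0.0
    for (p1, b1), (p2, b2) in zip(paired, paired[1:]):
        if p2 == p1 + 1:
            dg += STACK_DG.get(b1 + b2, 0.0)
    dg += HELIX_INIT_DG
    for _, base in (paired[0], paired[-1]):
        if base in ("A", "U"):
            dg += TERMINAL_AU_DG
    return float(dg)


def score_matches(
    sequences: Mapping[str, str],
    mirnas: Mapping[str, str],
    matches: Iterable[SeedMatch],
    circular: bool = True,
) -> List[SeedMatch]:
    """Attach alignment score and duplex energy to every match."""
    out = []
    for match in matches:
        seq = sequences[match.circ_id]
        mir = mirnas[match.mirna_id]
        out.append(replace(
            match,
            score=site_score(seq, match, mir, circular=circular),
            energy=site_energy(seq, match, mir, circular=circular),
        ))
    return out


def scan_all(
    sequences: Mapping[str, str],
    mirnas: Mapping[str, str],
    circular: bool = True,
    compute_scores: bool = False,
) -> List[SeedMatch]:
    """Scan every (sequence, miRNA) pair; optionally score each site."""
    matches: List[SeedMatch] = []
    for circ_id, seq in sequences.items():
        if len(seq) < 6:
            continue
        for mirna_id, mir in mirnas.items():
            matches.extend(
                scan(seq, mir, circular=circular, circ_id=circ_id, mirna_id=mirna_id)
            )
    if compute_scores:
        matches = score_matches(sequences, mirnas, matches, circular=circular)
    return matches


def filter_and_count(
    matches: Iterable[SeedMatch],
    min_score: float = DEFAULT_MIN_SCORE,
    max_dg: float = DEFAULT_MAX_DG,
) -> List[SeedSummary]:
    """Apply the category/score/energy gates and count unique circ-miRNA sites.

    Matches without a recognized category are dropped; surviving sites are
    counted per (circRNA, miRNA) pair and summaries are sorted by total
    occurrences, top to bottom.
    """
    counts: Dict[str, Dict[str, int]] = {}
    for match in matches:
        if match.category not in SEED_CATEGORIES:
            continue
        if min_score != -math.inf:
            if match.score is None:
                raise ValueError("score filter requested but match has no score")
            if match.score < min_score:
                continue
        if max_dg != math.inf:
            if match.energy is None:
                raise ValueError("energy filter requested but match has no energy")
            if match.energy > max_dg:
                continue
        counts.setdefault(match.circ_id, {}).setdefault(match.mirna_id, 0)
        counts[match.circ_id][match.mirna_id] += 1
    summaries = [SeedSummary(circ_id, per) for circ_id, per in counts.items()]
    summaries.sort(key=lambda s: (-s.total, s.circ_id))
    return summaries
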