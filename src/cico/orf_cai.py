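"""ORF finding, codon adaptation index, and Markov-null expected CAI.

ORFs are ATG-initiated, same-strand only, at least 150 nt by default, with
nested ORFs (an internal in-frame ATG inside a reported ORF) suppressed.
CAI is the geometric mean of relative codon adaptiveness w over the ORF's
codons, excluding stops. The significance threshold eCAI is the chosen
quantile (95% by default) of the CAI distribution of random sequences drawn
from a nucleotide Markov model fitted to the whole ORF pool, length-matched
to the pool; several independent runs are averaged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._seq import as_dna, STOP_CODONS
from .io_formats import CodonUsageTable, SYNONYMOUS_FAMILIES

DEFAULT_MIN_ORF_LEN = 150
DEFAULT_N_NULL = 500
DEFAULT_CONFIDENCE = 0.95
DEFAULT_MARKOV_ORDER = 1
DEFAULT_ECAI_REPEATS = 5

#: floor for relative adaptiveness so a zero-usage codon cannot zero the
#: geometric mean of an otherwise well-adapted ORF
W_FLOOR = 1e-3

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_STOP_CODES = {tuple(_BASE_INDEX[b] for b in c) for c in STOP_CODONS}


@dataclass
class OrfRecord:
    circ_id: str
    start: int  # 0-based on the mature sequence, includes the stop codon
    end: int
    sequence: str
    has_stop: bool
    cai: Optional[float] = None
    above_expected: Optional[bool] = None

    @property
    def length(self) -> int:
        return self.end - self.start


def find_orfs(
    sequence: str,
    min_len: int = DEFAULT_MIN_ORF_LEN,
    circular: bool = False,
    circ_id: str = "",
) -> List[OrfRecord]:
    """ATG-initiated, non-nested ORFs on the given strand only.

    An ORF runs from the first ATG after the previous stop to the next
    in-frame stop (included); an ORF reaching the sequence end without a stop
    is reported open-ended and flagged. In circular mode the doubled sequence
    is scanned, junction-spanning ORFs are reported once at their modular
    start, and lengths are capped at the sequence length.
    """
    s = as_dna(sequence)
    n = len(s)
    if n < 3:
        return []
    scan_seq = s + s if circular else s
    cap = n // 3 * 3
    found: Dict[int, OrfRecord] = {}  # modular start -> record
    for frame in range(3):
        i = frame
        start: Optional[int] = None
        while i + 3 <= len(scan_seq):
            codon = scan_seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                _add_orf(found, scan_seq, start, i + 3, True, n, cap, min_len,
                         circ_id, circular)
                start = None
            i += 3
        if start is not None:
            _add_orf(found, scan_seq, start, i, False, n, cap, min_len,
                     circ_id, circular)
    return sorted(found.values(), key=lambda o: (o.start, o.end))


def _add_orf(found, scan_seq, start, end, has_stop, n, cap, min_len,
             circ_id, circular) -> None:
    if circular:
        if start >= n:  # duplicate of a copy-one ORF
            return
        if end - start > cap:  # wraps more than once around the circle
            end = start + cap
            has_stop = False
    length = end - start
    if length < min_len:
        return
    key = start % n
    rec = OrfRecord(circ_id, start, end, scan_seq[start:end], has_stop)
    prev = found.get(key)
    if prev is None or rec.length > prev.length:
        found[key] = rec


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------

def relative_adaptiveness(usage: CodonUsageTable) -> Dict[str, float]:
    """w(codon) = usage / max usage in its synonymous family, floored at
    :data:`W_FLOOR`; single-codon families (Met, Trp) get w = 1."""
    w: Dict[str, float] = {}
    for fam in SYNONYMOUS_FAMILIES.values():
        peak = max(usage[c] for c in fam)
        if peak <= 0:
            raise ValueError(f"synonymous family {fam} has all-zero usage")
        for c in fam:
            w[c] = max(usage[c] / peak, W_FLOOR)
    return w


def cai(orf_sequence: str, w: Mapping[str, float]) -> float:
    """Geometric mean of w over the ORF's codons, excluding stop codons."""
    s = as_dna(orf_sequence)
    if len(s) % 3 != 0:
        raise ValueError(f"ORF length {len(s)} not divisible by 3")
    logs = []
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if codon in STOP_CODONS:
            continue
        logs.append(np.log(w[codon]))
    if not logs:
        raise ValueError("ORF contains no sense codons")
    return float(np.exp(np.mean(logs)))


# ---------------------------------------------------------------------------
# Markov null model and eCAI
# ---------------------------------------------------------------------------

@dataclass
class MarkovModel:
    """Order-k nucleotide Markov model (k in 0..2) over ACGT."""

    order: int
    initial: np.ndarray  # probability over 4**order starting contexts
    transition: np.ndarray  # (4**order, 4) row-stochastic

    @classmethod
    def fit(cls, pool: Sequence[str], order: int = DEFAULT_MARKOV_ORDER,
            pseudocount: float = 1.0) -> "MarkovModel":
        if not pool:
            raise ValueError("empty sequence pool")
        if not 0 <= order <= 2:
            raise ValueError(f"Markov order must be 0..2, got {order}")
        seqs = [as_dna(p) for p in pool]
        if len(set("".join(seqs))) < 2:
            raise ValueError("degenerate pool: fewer than two distinct bases")
        n_ctx = 4 ** order
        trans = np.full((n_ctx, 4), pseudocount)
        init = np.full(n_ctx, pseudocount)
        for s in seqs:
            codes = np.fromiter((_BASE_INDEX[b] for b in s if b != "N"), dtype=np.int64)
            if len(codes) <= order:
                continue
            if order == 0:
                ctxs = np.zeros(len(codes), dtype=np.int64)
                nexts = codes
            else:
                ctxs = np.zeros(len(codes) - order, dtype=np.int64)
                for k in range(order):
                    ctxs = ctxs * 4 + codes[k : len(codes) - order + k]
                nexts = codes[order:]
                init_ctx = int("".join(str(c) for c in codes[:order]), 4) if order else 0
                init[init_ctx] += 1
            np.add.at(trans, (ctxs, nexts), 1)
        if order == 0:
            init = np.ones(1)
        return cls(order, init / init.sum(), trans / trans.sum(axis=1, keepdims=True))

    def sample(self, lengths: Sequence[int], rng: np.random.Generator) -> np.ndarray:
        """Sample base-code matrix (n, max(lengths)); entries beyond each
        row's length are -1."""
        lengths = np.asarray(lengths, dtype=np.int64)
        n, max_len = len(lengths), int(lengths.max())
        out = np.full((n, max_len), -1, dtype=np.int8)
        ctx = rng.choice(len(self.initial), size=n, p=self.initial)
        if self.order > 0:
            # emit the context's bases
            for k in range(self.order):
                shift = 4 ** (self.order - 1 - k)
                out[:, k] = (ctx // shift) % 4
        cum = np.cumsum(self.transition, axis=1)
        for pos in range(self.order, max_len):
            u = rng.random(n)
            base = (u[:, None] > cum[ctx]).sum(axis=1).astype(np.int8)
            out[:, pos] = base
            if self.order > 0:
                ctx = (ctx * 4 + base) % (4 ** self.order)
        mask = np.arange(max_len)[None, :] >= lengths[:, None]
        out[mask] = -1
        return out

    def resample_codon(self, prev_base: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw replacement codons (k, 3) conditioned on the preceding base
        (order-1 style conditioning; -1 means sequence start)."""
        k = len(prev_base)
        codons = np.empty((k, 3), dtype=np.int8)
        if self.order == 0:
            cum = np.cumsum(self.transition[0])
            for j in range(3):
                codons[:, j] = (rng.random(k)[:, None] > cum[None, :]).sum(axis=1)
            return codons
        # condition each step on the single preceding base (sufficient for
        # order 1; an adequate approximation for order 2 repair draws)
        marg = self.transition if self.order == 1 else self._order1_marginal()
        prev = prev_base.copy()
        start_dist = np.cumsum(marg.mean(axis=0))
        for j in range(3):
            u = rng.random(k)
            base = np.empty(k, dtype=np.int8)
            fresh = prev < 0
            if fresh.any():
                base[fresh] = (u[fresh, None] > start_dist[None, :]).sum(axis=1)
            cond = ~fresh
            if cond.any():
                cum = np.cumsum(marg[prev[cond].astype(np.int64)], axis=1)
                base[cond] = (u[cond, None] > cum).sum(axis=1)
            codons[:, j] = base
            prev = base
        return codons

    def _order1_marginal(self) -> np.ndarray:
        # contexts are encoded b1*4 + b2; condition on the last base b2
        t = self.transition.reshape(4, 4, 4)
        return t.mean(axis=0)


def _strip_internal_stops(codes: np.ndarray, lengths: np.ndarray,
                          model: MarkovModel, rng: np.random.Generator,
                          max_iter: int = 100) -> np.ndarray:
    """Resample any internal stop codon in-place (final codon exempt)."""
    n_codons = lengths // 3
    for _ in range(max_iter):
        c0, c1, c2 = codes[:, 0::3], codes[:, 1::3], codes[:, 2::3]
        max_codons = c0.shape[1]
        idx = np.arange(max_codons)[None, :]
        internal = idx < (n_codons[:, None] - 1)
        is_stop = np.zeros_like(internal)
        for s0, s1, s2 in _STOP_CODES:
            is_stop |= (c0[:, :max_codons] == s0) & (c1[:, :max_codons] == s1) & (c2[:, :max_codons] == s2)
        bad = np.argwhere(internal & is_stop)
        if len(bad) == 0:
            return codes
        rows, cols = bad[:, 0], bad[:, 1]
        prev = np.where(cols > 0, codes[rows, np.maximum(cols * 3 - 1, 0)], -1).astype(np.int8)
        new = model.resample_codon(prev, rng)
        codes[rows, cols * 3] = new[:, 0]
        codes[rows, cols * 3 + 1] = new[:, 1]
        codes[rows, cols * 3 + 2] = new[:, 2]
    raise RuntimeError("could not remove internal stop codons from null sequences")


def _codes_to_seq(row: np.ndarray, length: int) -> str:
    return "".join(_BASES[b] for b in row[:length])


def null_cai_sample(
    pool: Sequence[str],
    w: Mapping[str, float],
    n_null: int,
    order: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """CAI values of n_null Markov-model sequences length-matched to the pool."""
    model = MarkovModel.fit(pool, order=order)
    pool_lengths = np.array([len(p) // 3 * 3 for p in pool])
    pool_lengths = pool_lengths[pool_lengths >= 3]
    if len(pool_lengths) == 0:
        raise ValueError("pool has no sequence of at least one codon")
    lengths = rng.choice(pool_lengths, size=n_null, replace=True)
    codes = model.sample(lengths, rng)
    codes = _strip_internal_stops(codes, lengths, model, rng)
    log_w = np.full((4, 4, 4), np.nan)
    for codon, value in w.items():
        i, j, k = (_BASE_INDEX[b] for b in codon)
        log_w[i, j, k] = np.log(value)
    for s0, s1, s2 in _STOP_CODES:
        log_w[s0, s1, s2] = np.nan  # stops excluded from the geometric mean
    out = np.empty(n_null)
    for i in range(n_null):
        L = lengths[i]
        cod = codes[i, :L].reshape(-1, 3)
        vals = log_w[cod[:, 0], cod[:, 1], cod[:, 2]]
        vals = vals[~np.isnan(vals)]
        out[i] = np.exp(vals.mean()) if len(vals) else 1.0
    return out


def ecai(
    pool: Sequence[str],
    w: Mapping[str, float],
    n_null: int = DEFAULT_N_NULL,
    order: int = DEFAULT_MARKOV_ORDER,
    confidence: float = DEFAULT_CONFIDENCE,
    seed: Optional[int] = None,
    n_repeats: int = DEFAULT_ECAI_REPEATS,
) -> float:
    """Expected CAI: the `confidence` quantile of the null CAI distribution,
    averaged over `n_repeats` independent runs of `n_null` sequences each."""
    if not pool:
        raise ValueError("empty ORF pool")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    root = np.random.default_rng(seed)
    values = []
    for sub in root.spawn(n_repeats):
        sample = null_cai_sample(pool, w, n_null=n_null, order=order, rng=sub)
        values.append(float(np.quantile(sample, confidence)))
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Shuffled control datasets
# ---------------------------------------------------------------------------

def shuffled_controls(
    genome: Mapping[str, str],
    transcripts: Sequence[str],
    lengths: Sequence[int],
    seed: Optional[int] = None,
) -> Tuple[List[str], List[str]]:
    """Length-matched random windows from the genome and the transcriptome.

    Returns (genomic set, transcriptomic set); each set has one window per
    requested length, drawn uniformly over feasible placements.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    genomic: List[str] = []
    for L in lengths:
        weights = np.array([max(0, len(genome[c]) - L + 1) for c in chroms], dtype=float)
        if weights.sum() == 0:
            raise ValueError(f"no chromosome can host a window of length {L}")
        c = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
        start = int(rng.integers(0, len(genome[c]) - L + 1))
        genomic.append(genome[c][start : start + L].upper())
    concat = "".join(t.upper() for t in transcripts)
    transcriptomic: List[str] = []
    for L in lengths:
        if len(concat) < L:
            raise ValueError(f"transcriptome shorter than requested window {L}")
        start = int(rng.integers(0, len(concat) - L + 1))
        transcriptomic.append(concat[start : start + L])
    return genomic, transcriptomic


def chi2_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Chi-squared test (1 df, no continuity correction) on [[a, b], [c, d]].

    statistic = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("both margins must be positive")
    statistic = n * (a * d - b * c) ** 2 / denom
    return float(statistic), float(stats.chi2.sf(statistic, df=1))
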