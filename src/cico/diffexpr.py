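"""Cross-population fold changes and trajectory classification.

Counts are normalized by median-of-ratios size factors, averaged within each
population, and each circRNA is labelled by its two consecutive transitions
(PP -> DP, DP -> N): U when FC >= 1.5, D when FC <= 0.67, F otherwise. The
nine two-letter labels (UU, UD, ..., FF) partition all calls; no FDR or any
other multiple-testing correction is applied.
"""
from __future__ import annotations

import itertools
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

UP_THRESHOLD = 1.5
DOWN_THRESHOLD = 0.67
DEFAULT_PSEUDOCOUNT = 0.5

TRAJECTORY_LABELS = tuple("".join(p) for p in itertools.product("UDF", repeat=2))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over rows with all-positive counts of
    count_ij / geometric_mean_i(counts).
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "add a pseudocount before computing size factors"
        )
    sub = mat[positive]
    log_gm = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_gm)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / size_factors(counts)


def fold_change(mean_a: float, mean_b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """(B + pc) / (A + pc); the pseudocount guards against zero means."""
    if mean_a + pseudocount == 0:
        raise ValueError("zero denominator: increase the pseudocount")
    return (mean_b + pseudocount) / (mean_a + pseudocount)


def _direction(fc: float, up: float, down: float) -> str:
    if fc >= up:
        return "U"
    if fc <= down:
        return "D"
    return "F"


def classify_trajectory(
    fc1: float, fc2: float, up: float = UP_THRESHOLD, down: float = DOWN_THRESHOLD
) -> str:
    """Two-letter label from the two transition fold changes (inclusive bounds)."""
    if not (down < up):
        raise ValueError(f"down threshold {down} must be below up threshold {up}")
    return _direction(fc1, up, down) + _direction(fc2, up, down)


def trajectory_calls(
    meta_counts: pd.DataFrame,
    design: Mapping[str, str],
    populations: Sequence[str] = ("PP", "DP", "N"),
    up: float = UP_THRESHOLD,
    down: float = DOWN_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Normalize, average per population, and classify every circRNA.

    Returns a frame indexed by circ id with the population means, the two
    fold changes and the trajectory label.
    """
    if len(populations) != 3:
        raise ValueError("trajectory classification expects exactly 3 populations")
    norm = normalize(meta_counts)
    means = {}
    for pop in populations:
        cols = [s for s in norm.columns if design[s] == pop]
        if not cols:
            raise ValueError(f"population {pop!r} has no samples")
        means[pop] = norm[cols].mean(axis=1)
    mean_df = pd.DataFrame(means)
    fc1 = (mean_df[populations[1]] + pseudocount) / (mean_df[populations[0]] + pseudocount)
    fc2 = (mean_df[populations[2]] + pseudocount) / (mean_df[populations[1]] + pseudocount)
    labels = [
        classify_trajectory(a, b, up=up, down=down) for a, b in zip(fc1, fc2)
    ]
    out = mean_df.copy()
    out["fc1"] = fc1
    out["fc2"] = fc2
    out["label"] = labels
    return out


def pattern_summary(labels: Sequence[str]) -> Dict[str, int]:
    """Counts per trajectory label; all nine labels are always present."""
    out = {lab: 0 for lab in TRAJECTORY_LABELS}
    for lab in labels:
        if lab not in out:
            raise ValueError(f"unknown trajectory label {lab!r}")
        out[lab] += 1
    return out
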