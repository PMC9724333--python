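"""Standardized mean differences and propensity-score overlap summaries.

The SMD is the design's running measure of patient heterogeneity, reported in
percent throughout:

    continuous:  |x̄1 − x̄2| / sqrt((s1² + s2²) / 2) × 100%
    binary:      |p1 − p2| / sqrt((p1(1−p1) + p2(1−p2)) / 2) × 100%

Binary variables use the p(1−p) population-variance form exactly; continuous
variables use the unbiased sample variance.  An SMD below 10% is the
conventional threshold for a minor between-group difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SMD_MINOR_THRESHOLD = 10.0  # percent


@dataclass
class GroupSummary:
    n: int
    mean: float | None = None
    variance: float | None = None
    proportion: float | None = None


def smd_continuous(mean1: float, var1: float, mean2: float, var2: float) -> float:
    """SMD (percent) between two groups of a continuous variable.

    With both variances zero the SMD is 0 for equal means and +inf otherwise.
    Symmetric in group order and invariant to a common affine rescaling.
    """
    if var1 < 0 or var2 < 0:
        raise ValueError("variances must be nonnegative")
    pooled = (var1 + var2) / 2.0
    diff = abs(mean1 - mean2)
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else math.inf
    return diff / math.sqrt(pooled) * 100.0


def smd_binary(p1: float, p2: float) -> float:
    """SMD (percent) between two groups of a binary variable."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportions must be in [0, 1], got {p}")
    pooled = (p1 * (1.0 - p1) + p2 * (1.0 - p2)) / 2.0
    diff = abs(p1 - p2)
    if pooled == 0.0:
        # both proportions degenerate (0 or 1); equal -> no difference,
        # opposite corners -> maximal, conventionally infinite
        return 0.0 if diff == 0.0 else math.inf
    return diff / math.sqrt(pooled) * 100.0


def balance_table(
    dataset: pd.DataFrame,
    roster: Mapping[str, str],
    exposure_col: str = "transfused",
) -> pd.DataFrame:
    """One SMD row per roster variable for the dataset's exposure split.

    ``roster`` maps variable name to ``"binary"`` or ``"continuous"``; rows
    keep roster order.  Variables missing a group entirely are marked
    incomputable (NaN SMD).  Missing values within a variable are dropped
    per-variable (complete-case per row).
    """
    exposure = dataset[exposure_col].astype(int)
    g1 = dataset[exposure == 1]
    g2 = dataset[exposure == 0]
    rows = []
    for name, kind in roster.items():
        if name not in dataset.columns:
            raise KeyError(f"unknown variable {name!r}")
        x1 = g1[name].dropna().to_numpy(dtype=float)
        x2 = g2[name].dropna().to_numpy(dtype=float)
        row: dict = {"variable": name, "kind": kind, "n1": len(x1), "n2": len(x2)}
        if len(x1) == 0 or len(x2) == 0:
            row.update(summary1=np.nan, summary2=np.nan,
                       smd_percent=np.nan, flag_gt10=False, computable=False)
        elif kind == "binary":
            p1, p2 = float(x1.mean()), float(x2.mean())
            s = smd_binary(p1, p2)
            row.update(summary1=p1, summary2=p2, smd_percent=s,
                       flag_gt10=s > SMD_MINOR_THRESHOLD, computable=True)
        elif kind == "continuous":
            v1 = float(x1.var(ddof=1)) if len(x1) > 1 else 0.0
            v2 = float(x2.var(ddof=1)) if len(x2) > 1 else 0.0
            s = smd_continuous(float(x1.mean()), v1, float(x2.mean()), v2)
            row.update(summary1=float(x1.mean()), summary2=float(x2.mean()),
                       smd_percent=s, flag_gt10=s > SMD_MINOR_THRESHOLD,
                       computable=True)
        else:
            raise ValueError(f"variable {name!r}: unknown kind {kind!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def overlap_summary(ps_by_group: Mapping[str, Sequence[float]]) -> dict:
    """Quantile table and overlap interval of propensity scores by group.

    The overlap interval is [max of group minima, min of group maxima]; a
    negative width means the groups' score ranges are disjoint.
    """
    quantiles = {}
    mins, maxs = [], []
    for name, scores in ps_by_group.items():
        arr = np.asarray(scores, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} has no propensity scores")
        q = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0])
        quantiles[name] = {
            "n": int(arr.size), "min": float(q[0]), "q1": float(q[1]),
            "median": float(q[2]), "q3": float(q[3]), "max": float(q[4]),
        }
        mins.append(q[0])
        maxs.append(q[4])
    lo, hi = float(max(mins)), float(min(maxs))
    return {
        "quantiles": quantiles,
        "overlap_low": lo,
        "overlap_high": hi,
        "overlap_width": hi - lo,
        "has_overlap": hi >= lo,
    }
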