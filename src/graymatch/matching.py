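"""Propensity-score estimation and greedy 1:1 nearest-neighbor caliper matching.

The propensity score is the modeled probability of receiving transfusion
given key covariates, fit by maximum-likelihood logistic regression.  Default
covariate sets follow the design: for the base population ASA >= 3,
pre-operative hemoglobin, operation >= 3 h, bleeding >= 500 mL and ICU
admission; the study population drops bleeding (excluded by construction).

Matching is greedy 1:1 nearest-neighbor without replacement.  The caliper is
0.2 standard deviations of the propensity score, with the SD pooled over both
groups and taken on the raw probability scale by default (the logit-scale
convention is available via ``caliper_on_logit``).  The processing order of
exposed members is random under the run seed (descending-score order is
selectable); distance ties break to the smallest control identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit

BASE_PS_COVARIATES = [
    "asa_ge3",
    "preop_hb",
    "operation_time_ge3h",
    "bleeding_ge500ml",
    "icu_admission",
]
STUDY_PS_COVARIATES = [
    "asa_ge3",
    "preop_hb",
    "operation_time_ge3h",
    "icu_admission",
]


class SeparationError(RuntimeError):
    """The logistic likelihood is unbounded (quasi-)perfect separation."""


class ConvergenceError(RuntimeError):
    """The logistic fit did not converge within the iteration budget."""


@dataclass
class PropensityModelSpec:
    population: str  # "base" | "study" | custom label
    covariates: list[str]
    coefficients: Optional[pd.Series] = None
    converged: bool = False
    n_used: int = 0
    n_dropped_incomplete: int = 0

    @classmethod
    def for_population(cls, population: str) -> "PropensityModelSpec":
        covs = {"base": BASE_PS_COVARIATES, "study": STUDY_PS_COVARIATES}[population]
        return cls(population=population, covariates=list(covs))


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # exposed_id, control_id, distance
    caliper: float
    ps_sd: float
    caliper_multiplier: float
    matching_rate_exposed: float
    matching_rate_control: float
    unmatched_exposed: list = field(default_factory=list)
    unmatched_control: list = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "caliper": self.caliper,
            "ps_sd": self.ps_sd,
            "caliper_multiplier": self.caliper_multiplier,
            "matching_rate_exposed": self.matching_rate_exposed,
            "matching_rate_control": self.matching_rate_control,
            "n_unmatched_exposed": len(self.unmatched_exposed),
            "n_unmatched_control": len(self.unmatched_control),
        }


def _fit_logistic(y: np.ndarray, X: pd.DataFrame):
    """MLE logistic fit with explicit separation / convergence errors."""
    import warnings

    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationWarning,
    )

    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            # non-convergence and overflow surface as typed errors below
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(disp=0, maxiter=100)
    except PerfectSeparationWarning as e:
        raise SeparationError(
            f"perfect separation among covariates {list(X.columns)}"
        ) from e
    except np.linalg.LinAlgError as e:  # singular design
        raise SeparationError(f"logistic design is singular: {e}") from e
    except Exception as e:
        if "Perfect separation" in str(e) or "separation" in str(e).lower():
            raise SeparationError(
                f"perfect separation among covariates {list(X.columns)}"
            ) from e
        raise
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"logistic fit did not converge in 100 iterations; "
            f"retvals={res.mle_retvals}"
        )
    if np.max(np.abs(res.params.to_numpy())) > 50:
        raise SeparationError(
            f"quasi-separation: unbounded coefficient among {list(X.columns)}; "
            f"params={res.params.to_dict()}"
        )
    return res


def fit_propensity(
    dataset: pd.DataFrame,
    spec: PropensityModelSpec,
    exposure_col: str = "transfused",
) -> tuple[pd.Series, PropensityModelSpec]:
    """Fit the propensity model; returns scores indexed by patient_id.

    Records with a missing covariate are dropped (complete-case) and their
    count stored on the returned spec.
    """
    cols = [exposure_col, *spec.covariates]
    missing = [c for c in cols if c not in dataset.columns]
    if missing:
        raise KeyError(f"dataset lacks columns {missing}")
    sub = dataset[["patient_id", *cols]].dropna(subset=spec.covariates)
    spec.n_dropped_incomplete = len(dataset) - len(sub)
    spec.n_used = len(sub)
    y = sub[exposure_col].astype(int).to_numpy()
    X = sm.add_constant(sub[spec.covariates].astype(float), has_constant="add")
    res = _fit_logistic(y, X)
    spec.coefficients = res.params
    spec.converged = True
    scores = pd.Series(np.asarray(res.predict(X)), index=sub["patient_id"].to_numpy(),
                       name="propensity_score")
    return scores, spec


def match(
    scores: Sequence[float],
    exposure: Sequence[int],
    ids: Optional[Sequence] = None,
    caliper_multiplier: float = 0.2,
    seed: int = 0,
    order: str = "random",
    caliper_on_logit: bool = False,
    caliper: Optional[float] = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor caliper matching without replacement.

    ``scores`` and ``exposure`` are parallel; ``ids`` default to positions.
    Caliper = ``caliper_multiplier`` x SD of all scores pooled over both
    groups (ddof=1), on the probability scale unless ``caliper_on_logit``;
    an explicit ``caliper`` overrides the SD rule.  Exposed members are
    processed in seeded random order (or by descending score); each takes
    the nearest still-unmatched control within the caliper, ties to the
    smallest control id.
    """
    s = np.asarray(scores, dtype=float)
    e = np.asarray(exposure, dtype=int)
    pid = np.arange(len(s)) if ids is None else np.asarray(ids)
    if s.shape != e.shape:
        raise ValueError("scores and exposure must have equal length")
    if not (e == 1).any() or not (e == 0).any():
        raise ValueError("both an exposed and a control group are required")

    metric = logit(np.clip(s, 1e-12, 1 - 1e-12)) if caliper_on_logit else s
    sd = float(np.std(metric, ddof=1))
    if caliper is None:
        caliper = caliper_multiplier * sd

    exp_idx = np.flatnonzero(e == 1)
    ctl_idx = np.flatnonzero(e == 0)
    if order == "random":
        exp_idx = exp_idx[np.random.default_rng(seed).permutation(exp_idx.size)]
    elif order == "descending":
        o = np.argsort(-metric[exp_idx], kind="stable")
        exp_idx = exp_idx[o]
    else:
        raise ValueError(f"order must be 'random' or 'descending', got {order!r}")

    ctl_scores = metric[ctl_idx]
    ctl_ids = pid[ctl_idx]
    available = np.ones(ctl_idx.size, dtype=bool)
    pairs = []
    for i in exp_idx:
        if not available.any():
            break
        d = np.abs(ctl_scores - metric[i])
        d[~available] = np.inf
        dmin = d.min()
        if dmin > caliper:
            continue
        cand = np.flatnonzero(d == dmin)
        j = cand[np.argmin(ctl_ids[cand])]  # tie-break: smallest control id
        available[j] = False
        pairs.append((pid[i], ctl_ids[j], float(dmin)))

    pairs_df = pd.DataFrame(pairs, columns=["exposed_id", "control_id", "distance"])
    matched_exp = set(pairs_df["exposed_id"])
    matched_ctl = set(pairs_df["control_id"])
    return MatchResult(
        pairs=pairs_df,
        caliper=caliper,
        ps_sd=sd,
        caliper_multiplier=caliper_multiplier,
        matching_rate_exposed=100.0 * len(pairs) / exp_idx.size,
        matching_rate_control=100.0 * len(pairs) / ctl_idx.size,
        unmatched_exposed=[x for x in pid[e == 1] if x not in matched_exp],
        unmatched_control=[x for x in ctl_ids if x not in matched_ctl],
    )
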