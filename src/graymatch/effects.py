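"""Transfusion-outcome association as odds ratios with Wald 95% CIs.

``crude_or`` is the closed-form 2x2 cross-product oracle; ``fit_outcome_model``
is the general multivariable logistic route (maximum likelihood, Wald
inference on the log scale, two-tailed alpha = 0.05).  With no adjustment
covariates the two agree to optimizer tolerance, which the test suite uses as
an equivalence check.

Default adjustment sets follow the design: base population — ASA >= 3,
age >= 75, preoperative comorbidity, preoperative hemoglobin, operation
>= 3 h, bleeding >= 500 mL, ICU admission; study population — the same minus
bleeding and ICU.  "Preoperative comorbidity" is operationalized as any of
the five comorbidity flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .matching import ConvergenceError, SeparationError, _fit_logistic

COMORBIDITY_FLAGS = [
    "hypertension",
    "coronary_heart_disease",
    "diabetes",
    "stroke",
    "copd",
]

BASE_ADJUSTMENT = [
    "asa_ge3",
    "age_ge75",
    "any_comorbidity",
    "preop_hb",
    "operation_time_ge3h",
    "bleeding_ge500ml",
    "icu_admission",
]
STUDY_ADJUSTMENT = [
    "asa_ge3",
    "age_ge75",
    "any_comorbidity",
    "preop_hb",
    "operation_time_ge3h",
]

Z_975 = stats.norm.ppf(0.975)


class ZeroCellError(ValueError):
    """A 2x2 cell is zero; the cross-product OR is undefined."""


@dataclass
class EffectEstimate:
    label: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    covariates: list[str] = field(default_factory=list)
    n_dropped_incomplete: int = 0

    def covers_null(self) -> bool:
        return self.ci_low <= 1.0 <= self.ci_high

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
            "n_events": self.n_events,
            "covariates": list(self.covariates),
            "n_dropped_incomplete": self.n_dropped_incomplete,
        }


def crude_or(a: int, b: int, c: int, d: int, continuity: bool = False,
             label: str = "crude") -> EffectEstimate:
    """Crude odds ratio from the 2x2 table

    ==============  ======  =========
    .               event   no event
    exposed         a       b
    control         c       d
    ==============  ======  =========

    OR = ad / bc with a log-scale Wald CI, SE = sqrt(1/a + 1/b + 1/c + 1/d).
    A zero cell raises ``ZeroCellError`` unless ``continuity`` adds 0.5 to
    every cell (Haldane-Anscombe).
    """
    cells = [a, b, c, d]
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError(f"cell counts must be nonnegative integers, got {cells}")
    if any(x == 0 for x in cells):
        if not continuity:
            raise ZeroCellError(
                f"zero cell in 2x2 table {cells}; pass continuity=True for the "
                "0.5 continuity-corrected estimate"
            )
        a, b, c, d = (x + 0.5 for x in cells)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    z = log_or / se
    return EffectEstimate(
        label=label,
        odds_ratio=or_,
        ci_low=math.exp(log_or - Z_975 * se),
        ci_high=math.exp(log_or + Z_975 * se),
        p_value=2.0 * stats.norm.sf(abs(z)),
        n=int(sum(cells)),
        n_events=int(cells[0] + cells[2]),
        covariates=[],
    )


def add_derived_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Add age_ge75 and any_comorbidity columns where derivable."""
    df = df.copy()
    if "age_ge75" not in df.columns and "age_years" in df.columns:
        df["age_ge75"] = (df["age_years"] >= 75).astype(int)
    if "any_comorbidity" not in df.columns:
        present = [c for c in COMORBIDITY_FLAGS if c in df.columns]
        if present:
            df["any_comorbidity"] = df[present].fillna(0).astype(int).max(axis=1)
    return df


def fit_outcome_model(
    dataset: pd.DataFrame,
    outcome: pd.Series | str,
    exposure_col: str = "transfused",
    covariates: Sequence[str] = (),
    label: str = "adjusted",
) -> EffectEstimate:
    """Adjusted odds ratio of exposure on outcome by ML logistic regression.

    Complete-case: rows missing any covariate are dropped and counted.
    Raises ``SeparationError`` / ``ConvergenceError`` on pathological fits
    and ``ValueError`` when the outcome is degenerate (no events or no
    non-events after exclusions).
    """
    df = add_derived_covariates(dataset)
    if isinstance(outcome, str):
        y_all = df[outcome]
    else:
        y_all = outcome.reset_index(drop=True)
        df = df.reset_index(drop=True)
    covariates = list(covariates)
    missing = [c for c in [exposure_col, *covariates] if c not in df.columns]
    if missing:
        raise KeyError(f"dataset lacks columns {missing}")
    work = df[[exposure_col, *covariates]].copy()
    work["__y"] = np.asarray(y_all, dtype=float)
    complete = work.dropna()
    n_dropped = len(work) - len(complete)
    y = complete["__y"].astype(int).to_numpy()
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise ValueError(
            f"degenerate outcome: {n_events} events among {len(y)} complete cases"
        )
    X = sm.add_constant(
        complete[[exposure_col, *covariates]].astype(float), has_constant="add"
    )
    res = _fit_logistic(y, X)
    beta = float(res.params[exposure_col])
    se = float(res.bse[exposure_col])
    return EffectEstimate(
        label=label,
        odds_ratio=math.exp(beta),
        ci_low=math.exp(beta - Z_975 * se),
        ci_high=math.exp(beta + Z_975 * se),
        p_value=float(res.pvalues[exposure_col]),
        n=len(y),
        n_events=n_events,
        covariates=covariates,
        n_dropped_incomplete=n_dropped,
    )


__all__ = [
    "EffectEstimate",
    "ZeroCellError",
    "SeparationError",
    "ConvergenceError",
    "crude_or",
    "fit_outcome_model",
    "add_derived_covariates",
    "BASE_ADJUSTMENT",
    "STUDY_ADJUSTMENT",
]
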