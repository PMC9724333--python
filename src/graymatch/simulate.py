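"""Seeded synthetic perioperative cohort generator.

Emulates a multicenter cohort of older general-surgery inpatients in which
red-cell transfusion is decided primarily on the current hemoglobin level, and
in which the indications for transfusion (anemia, mass bleeding, poor ASA
status, long operations) independently predict adverse outcomes.  This is the
classic confounding-by-indication structure: with a truly null transfusion
effect the naive transfused-vs-not comparison still shows a strongly elevated
odds ratio.

Time is discrete: measurement occasions are admission, pre-op, and
post-operative days 1..k.  A transfusion decision is evaluated at every
post-operative occasion as a logistic function of the lowest hemoglobin
observed so far; the first success is the "initial transfusion" and is
recorded strictly between that occasion and the next (index j + 0.5).  Each
transfusion raises all subsequent measurements by ``transfusion_hb_gain``.

The composite-outcome model uses the *counterfactual* (never-transfused)
hemoglobin nadir, so ``true_transfusion_log_or`` is exactly the causal effect
of transfusion and 0 is an exact null.

All model coefficients are free parameters of this artifact, calibrated once
by simulation to the target marginal rates; the intercepts of the transfusion
and outcome models are solved analytically at run time so the configured
marginal rates are hit at any sample size.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimulationConfig

# Transfusion-decision logistic coefficients (per g/dL below the 9 g/dL
# reference, and for bleeding >=500 mL, ASA >= 3, operation >= 3 h).
TX_HB_REF = 9.0
TX_COEF_HB = 1.4
TX_COEF_BLEED = 1.6
TX_COEF_ASA = 0.7
TX_COEF_OP = 0.6

# Composite-outcome logistic coefficients.  The anemia/bleeding/ASA block is
# scaled by ``confounding_strength``; age and comorbidity are outcome-only
# risk factors and do not enter the transfusion model.
#
# Anemia risk is a linear spline in the nadir hemoglobin: no excess risk
# above 10 g/dL, a shallow gradient through the mild-anemia gray zone
# (clinical equipoise is what makes it a gray zone), and a steep additional
# gradient below the restrictive threshold of 7.5 g/dL where anemia is no
# longer compensated.
OUT_HB_REF = 10.0
OUT_HB_SEVERE_KNOT = 7.5
OUT_COEF_HB_MILD = 0.18
OUT_COEF_HB_SEVERE = 1.2
OUT_COEF_BLEED = 1.0
OUT_COEF_ASA = 0.8
OUT_COEF_AGE75 = 0.5
OUT_COEF_COMORBID = 0.4

COMORBIDITY_FLAGS = [
    "hypertension",
    "coronary_heart_disease",
    "diabetes",
    "stroke",
    "copd",
]

#: conditional split of the composite outcome into its reported components
OUTCOME_CATEGORIES = ["death", "ischemic_event", "infection", "other_complication"]
OUTCOME_CATEGORY_PROBS = [0.18, 0.13, 0.50, 0.19]

PATIENT_COLUMNS_DOC = {
    "patient_id": "integer identifier",
    "age_years": "age at admission, years (cohort is 60+)",
    "male": "1 = male",
    "smoking": "current smoker flag",
    "bmi": "body mass index, kg/m^2",
    "hypertension": "comorbidity flag",
    "coronary_heart_disease": "comorbidity flag",
    "diabetes": "comorbidity flag",
    "stroke": "comorbidity flag",
    "copd": "comorbidity flag",
    "asa_ge3": "ASA physical status >= 3",
    "albumin_lt35": "serum albumin < 35 g/L",
    "high_creatinine": "creatinine > 84 umol/L (women) / > 104 umol/L (men)",
    "wbc_gt10": "white cell count > 10e9/L",
    "preop_hb": "pre-operative hemoglobin, g/dL",
    "operation_time_ge3h": "operation lasted >= 3 h (may be missing)",
    "bleeding_ge500ml": "intraoperative blood loss >= 500 mL",
    "icu_admission": "postoperative ICU admission",
    "major_surgery": "anesthesiologist present during surgery",
    "stay_hours": "length of hospital stay, hours",
    "high_altitude": "residence at 2000-5000 m above sea level",
    "transfused": "received >= 1 red-cell transfusion during the stay",
    "death": "in-hospital or 30-day death",
    "ischemic_event": "myocardial infarction / stroke / acute renal failure",
    "infection": "surgical site infection / pneumonia / sepsis / UTI",
    "other_complication": "other in-hospital complication",
}


def default_config(**overrides) -> SimulationConfig:
    """Config whose simulated base population matches the emulated cohort's
    marginal distributions (transfusion rate 10.8%, pre-op Hb 13.5 (1.8) g/dL,
    male 52%, ASA>=3 23%, ...)."""
    return SimulationConfig(**overrides)


def _solve_intercept_any_event(lp: np.ndarray, target: float) -> float:
    """Intercept b0 such that mean_i [1 - prod_j (1 - expit(b0 + lp_ij))]
    equals ``target``.  ``lp`` is (n, k) of intercept-free linear predictors.
    Monotone in b0, solved by bisection."""
    lo, hi = -25.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        rate = float(np.mean(1.0 - np.prod(1.0 - expit(mid + lp), axis=1)))
        if rate < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _solve_intercept_rate(lp: np.ndarray, target: float) -> float:
    """Intercept b0 such that mean expit(b0 + lp) equals ``target``."""
    lo, hi = -25.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if float(np.mean(expit(mid + lp))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns
    -------
    patients, hemoglobin, transfusions, truth : DataFrames
        ``patients`` has one row per admission (see ``PATIENT_COLUMNS_DOC``);
        ``hemoglobin`` is long-format (patient_id, occasion, hb_gdl);
        ``transfusions`` is (patient_id, occasion) with half-integer occasion
        indices; ``truth`` carries the latent generative quantities used by
        calibration tests.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    m = config.covariate_margins

    def bern(name: str) -> np.ndarray:
        return (rng.random(n) < m[name]).astype(np.int8)

    patients = pd.DataFrame({"patient_id": np.arange(n, dtype=np.int64)})
    age = 60.0 + rng.exponential(8.2, n)
    patients["age_years"] = np.minimum(age, 99.0).round(0).astype(int)
    patients["male"] = bern("male")
    patients["smoking"] = bern("smoking")
    patients["bmi"] = np.clip(rng.normal(23.4, 3.46, n), 13.0, 45.0).round(1)
    for flag in COMORBIDITY_FLAGS:
        patients[flag] = bern(flag)
    patients["asa_ge3"] = bern("asa_ge3")
    patients["albumin_lt35"] = bern("albumin_lt35")
    patients["high_creatinine"] = bern("high_creatinine")
    patients["wbc_gt10"] = bern("wbc_gt10")
    preop_hb = np.clip(
        rng.normal(config.hb_preop_mean, config.hb_preop_sd, n), 4.0, 19.0
    )
    patients["preop_hb"] = preop_hb.round(1)

    op_long = bern("operation_time_ge3h")
    bleed_p = np.where(
        op_long == 1, config.bleed_prob_given_long_op, config.bleed_prob_given_short_op
    )
    bleed = (rng.random(n) < bleed_p).astype(np.int8)
    patients["operation_time_ge3h"] = op_long.astype(float)
    patients["bleeding_ge500ml"] = bleed
    asa = patients["asa_ge3"].to_numpy()

    icu_lp = 0.9 * asa + 0.8 * op_long + 1.5 * bleed
    icu_b0 = _solve_intercept_rate(icu_lp[:, None], 0.095)
    patients["icu_admission"] = (rng.random(n) < expit(icu_b0 + icu_lp)).astype(np.int8)
    patients["major_surgery"] = bern("major_surgery")
    patients["stay_hours"] = np.exp(rng.normal(np.log(96.0), 0.8, n)).round(1)
    patients["high_altitude"] = bern("high_altitude")

    # --- hemoglobin trajectory without transfusion (counterfactual) --------
    schedule = config.measurement_schedule
    k = len(schedule)
    n_post = k - 2
    hb_cf = np.empty((n, k))
    hb_cf[:, 0] = preop_hb + rng.normal(0.0, 0.3, n)
    hb_cf[:, 1] = preop_hb
    drop = np.clip(
        1.2 + 0.8 * op_long + config.hb_drop_per_bleed * bleed + rng.normal(0.0, 0.7, n),
        0.0,
        None,
    )
    hb_cf[:, 2] = hb_cf[:, 1] - drop
    for j in range(3, k):
        hb_cf[:, j] = hb_cf[:, j - 1] + rng.normal(0.35, 0.25, n)
    hb_cf = np.clip(hb_cf, 3.0, 20.0)
    nadir_cf = hb_cf.min(axis=1)

    # --- transfusion decisions at post-operative occasions ------------------
    # Intercept solved so that P(ever transfused) hits the target exactly in
    # expectation; the running-minimum of the counterfactual trajectory equals
    # the observed one up to the first transfusion, so the solution is exact
    # for the first event.
    runmin_cf = np.minimum.accumulate(hb_cf, axis=1)[:, 2:]
    tx_lp = (
        TX_COEF_HB * (TX_HB_REF - runmin_cf)
        + (TX_COEF_BLEED * bleed + TX_COEF_ASA * asa + TX_COEF_OP * op_long)[:, None]
    )
    tx_b0 = _solve_intercept_any_event(tx_lp, config.target_transfusion_rate)

    hb_obs = hb_cf.copy()
    gain = np.zeros(n)
    tx_patient: list[np.ndarray] = []
    tx_occasion: list[np.ndarray] = []
    decision_u = rng.random((n, n_post))
    for jj in range(n_post):
        j = jj + 2
        hb_obs[:, j] = np.clip(hb_cf[:, j] + gain, 3.0, 20.0)
        runmin = hb_obs[:, : j + 1].min(axis=1)
        p = expit(
            tx_b0
            + TX_COEF_HB * (TX_HB_REF - runmin)
            + TX_COEF_BLEED * bleed
            + TX_COEF_ASA * asa
            + TX_COEF_OP * op_long
        )
        hit = decision_u[:, jj] < p
        ids = np.flatnonzero(hit)
        tx_patient.append(ids)
        tx_occasion.append(np.full(ids.size, j + 0.5))
        gain[hit] += config.transfusion_hb_gain

    tx = pd.DataFrame(
        {
            "patient_id": np.concatenate(tx_patient) if tx_patient else np.array([], int),
            "occasion": np.concatenate(tx_occasion) if tx_occasion else np.array([]),
        }
    ).sort_values(["patient_id", "occasion"], kind="stable", ignore_index=True)
    transfused = np.zeros(n, dtype=np.int8)
    transfused[np.unique(tx["patient_id"].to_numpy())] = 1
    patients["transfused"] = transfused

    # --- composite outcome ---------------------------------------------------
    comorbid_any = patients[COMORBIDITY_FLAGS].to_numpy().max(axis=1)
    age75 = (patients["age_years"].to_numpy() >= 75).astype(np.int8)
    anemia_burden = OUT_COEF_HB_MILD * np.clip(
        OUT_HB_REF - nadir_cf, 0.0, OUT_HB_REF - OUT_HB_SEVERE_KNOT
    ) + OUT_COEF_HB_SEVERE * np.clip(OUT_HB_SEVERE_KNOT - nadir_cf, 0.0, None)
    confounded_lp = anemia_burden + OUT_COEF_BLEED * bleed + OUT_COEF_ASA * asa
    out_lp = (
        config.confounding_strength * confounded_lp
        + OUT_COEF_AGE75 * age75
        + OUT_COEF_COMORBID * comorbid_any
    )
    out_b0 = _solve_intercept_rate(
        (out_lp + config.true_transfusion_log_or * transfused)[:, None],
        config.target_outcome_rate,
    )
    p_outcome = expit(out_b0 + out_lp + config.true_transfusion_log_or * transfused)
    outcome = (rng.random(n) < p_outcome).astype(np.int8)

    for col in OUTCOME_CATEGORIES:
        patients[col] = np.int8(0)
    cat = rng.choice(len(OUTCOME_CATEGORIES), size=n, p=OUTCOME_CATEGORY_PROBS)
    for i, col in enumerate(OUTCOME_CATEGORIES):
        patients.loc[(outcome == 1) & (cat == i), col] = 1

    if config.missing_operation_time_rate > 0:
        miss = rng.random(n) < config.missing_operation_time_rate
        patients.loc[miss, "operation_time_ge3h"] = np.nan

    hb = pd.DataFrame(
        {
            "patient_id": np.repeat(np.arange(n, dtype=np.int64), k),
            "occasion": np.tile(np.arange(k), n),
            "occasion_label": np.tile(np.asarray(schedule, dtype=object), n),
            "hb_gdl": hb_obs.round(2).ravel(),
        }
    )

    truth = pd.DataFrame(
        {
            "patient_id": np.arange(n, dtype=np.int64),
            "linear_predictor_outcome": out_b0
            + out_lp
            + config.true_transfusion_log_or * transfused,
            "was_confounded": (config.confounding_strength > 0)
            & ((bleed == 1) | (nadir_cf < OUT_HB_REF)),
            "counterfactual_outcome_prob_untransfused": expit(out_b0 + out_lp),
            "nadir_counterfactual": nadir_cf,
        }
    )
    return patients, hb, tx, truth


def write_cohort_csvs(
    outdir: Union[str, Path],
    patients: pd.DataFrame,
    hb: pd.DataFrame,
    tx: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the generated tables to ``outdir`` as CSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("patients", patients),
        ("hemoglobin", hb),
        ("transfusions", tx),
        ("truth", truth),
    ]:
        if df is None:
            continue
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
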