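"""Four-dataset analysis workflow and report generation.

Runs the full design on one cohort: the base population before and after
propensity-score matching (Base Match-, Base Match+) emulates a conventional
observational analysis; the stable-hemoglobin study population before and
after matching (Study Match-, Study Match+) demonstrates the
hemoglobin-based design.  Each dataset gets a descriptive summary, a
covariate balance table, a propensity-score overlap summary, a match result
where applicable, and crude plus adjusted effect estimates.  Every exclusion
count is kept in the run manifest.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .balance import balance_table, overlap_summary
from .cohort import (
    CohortDefinition,
    build_base_population,
    build_study_population,
    define_composite_outcome,
    descriptive_summary,
    extract_triggers,
)
from .config import RunConfig
from .effects import (
    BASE_ADJUSTMENT,
    STUDY_ADJUSTMENT,
    ConvergenceError,
    SeparationError,
    ZeroCellError,
    add_derived_covariates,
    crude_or,
    fit_outcome_model,
)
from .matching import MatchResult, PropensityModelSpec, fit_propensity, match
from .simulate import simulate_cohort

FOUR_DATASETS = ["BaseMatchMinus", "BaseMatchPlus", "StudyMatchMinus", "StudyMatchPlus"]

#: descriptive / balance roster mirroring the baseline characteristics table
COVARIATE_ROSTER: dict[str, str] = {
    "male": "binary",
    "age_ge75": "binary",
    "smoking": "binary",
    "bmi": "continuous",
    "hypertension": "binary",
    "coronary_heart_disease": "binary",
    "diabetes": "binary",
    "stroke": "binary",
    "copd": "binary",
    "asa_ge3": "binary",
    "albumin_lt35": "binary",
    "high_creatinine": "binary",
    "wbc_gt10": "binary",
    "preop_hb": "continuous",
    "operation_time_ge3h": "binary",
    "bleeding_ge500ml": "binary",
    "icu_admission": "binary",
}


class StageError(RuntimeError):
    """An analysis stage failed; carries stage name and cohort-size context."""


def _load_inputs(config: RunConfig):
    if config.simulate:
        sim = config.simulation.model_copy(update={"seed": config.seed})
        patients, hb, tx, truth = simulate_cohort(sim)
        return patients, hb, tx, truth
    patients = pd.read_csv(config.patients_csv)
    hb = pd.read_csv(config.hemoglobin_csv)
    tx = pd.read_csv(config.transfusions_csv)
    return patients, hb, tx, None


def _matched_subset(df: pd.DataFrame, mr: MatchResult) -> pd.DataFrame:
    keep = pd.concat([mr.pairs["exposed_id"], mr.pairs["control_id"]])
    return df[df["patient_id"].isin(set(keep))].reset_index(drop=True)


def _analyze_dataset(
    label: str,
    df: pd.DataFrame,
    adjustment: list[str],
    roster: dict[str, str],
) -> dict:
    out: dict = {"label": label, "n": len(df),
                 "n_exposed": int(df["transfused"].sum())}
    out["members"] = df[["patient_id", "transfused"]].reset_index(drop=True)
    out["descriptive"] = descriptive_summary(df, roster)
    out["balance"] = balance_table(df, roster)
    t = df["transfused"].astype(int)
    y = df["composite_outcome"].astype(int)
    try:
        out["crude"] = crude_or(
            int(((t == 1) & (y == 1)).sum()), int(((t == 1) & (y == 0)).sum()),
            int(((t == 0) & (y == 1)).sum()), int(((t == 0) & (y == 0)).sum()),
            label=label,
        ).to_dict()
    except (ValueError, ZeroCellError) as e:
        out["crude"] = {"label": label, "not_estimable": True, "reason": str(e)}
    try:
        out["effect"] = fit_outcome_model(
            df, "composite_outcome", covariates=adjustment, label=label
        ).to_dict()
        out["estimable"] = True
    except (ValueError, SeparationError, ConvergenceError) as e:
        out["effect"] = {"label": label, "not_estimable": True, "reason": str(e)}
        out["estimable"] = False
    return out


def _match_stage(
    df: pd.DataFrame, population: str, config: RunConfig
) -> tuple[pd.Series, MatchResult, PropensityModelSpec]:
    spec = PropensityModelSpec.for_population(population)
    scores, spec = fit_propensity(df, spec)
    sub = df[df["patient_id"].isin(scores.index)]
    mr = match(
        scores.loc[sub["patient_id"]].to_numpy(),
        sub["transfused"].to_numpy(),
        ids=sub["patient_id"].to_numpy(),
        caliper_multiplier=config.caliper_multiplier,
        seed=config.seed,
        order=config.match_order,
        caliper_on_logit=config.caliper_on_logit,
    )
    return scores, mr, spec


def run_four_dataset_analysis(config: RunConfig) -> dict:
    """Run the complete workflow; returns the report bundle.

    The bundle maps each dataset label to its summaries and estimates and
    carries a manifest sufficient to reproduce the run (seed, versions,
    filter accounting, window).  Deterministic given the seed.
    """
    patients, hb, tx, truth = _load_inputs(config)
    patients = add_derived_covariates(patients)
    patients["composite_outcome"] = define_composite_outcome(patients)

    stage = "base_population"
    try:
        base, base_def = build_base_population(patients)
        stage = "trigger_extraction"
        triggers = extract_triggers(
            hb[hb["patient_id"].isin(base["patient_id"])],
            tx[tx["patient_id"].isin(base["patient_id"])],
        )
        stage = "study_population"
        study, study_def = build_study_population(base, triggers, config.hb_window)

        bundle: dict = {
            "datasets": {},
            "definitions": {"base": base_def.to_dict(), "study": study_def.to_dict()},
            "sensitivity": [],
        }

        stage = "BaseMatchMinus"
        bundle["datasets"]["BaseMatchMinus"] = _analyze_dataset(
            "BaseMatchMinus", base, BASE_ADJUSTMENT, COVARIATE_ROSTER
        )
        stage = "BaseMatchPlus"
        scores_b, mr_b, spec_b = _match_stage(base, "base", config)
        bundle["datasets"]["BaseMatchMinus"]["overlap"] = overlap_summary({
            "exposed": scores_b[base.set_index("patient_id")["transfused"].loc[scores_b.index] == 1],
            "control": scores_b[base.set_index("patient_id")["transfused"].loc[scores_b.index] == 0],
        })
        base_plus = _matched_subset(base, mr_b)
        d = _analyze_dataset("BaseMatchPlus", base_plus, BASE_ADJUSTMENT, COVARIATE_ROSTER)
        d["match"] = mr_b
        d["ps_spec"] = spec_b
        bundle["datasets"]["BaseMatchPlus"] = d

        stage = "StudyMatchMinus"
        bundle["datasets"]["StudyMatchMinus"] = _analyze_dataset(
            "StudyMatchMinus", study, STUDY_ADJUSTMENT, COVARIATE_ROSTER
        )
        stage = "StudyMatchPlus"
        scores_s, mr_s, spec_s = _match_stage(study, "study", config)
        bundle["datasets"]["StudyMatchMinus"]["overlap"] = overlap_summary({
            "exposed": scores_s[study.set_index("patient_id")["transfused"].loc[scores_s.index] == 1],
            "control": scores_s[study.set_index("patient_id")["transfused"].loc[scores_s.index] == 0],
        })
        study_plus = _matched_subset(study, mr_s)
        d = _analyze_dataset("StudyMatchPlus", study_plus, STUDY_ADJUSTMENT, COVARIATE_ROSTER)
        d["match"] = mr_s
        d["ps_spec"] = spec_s
        bundle["datasets"]["StudyMatchPlus"] = d

        for window in config.sensitivity_windows:
            stage = f"sensitivity_{window}"
            s_df, s_def = build_study_population(base, triggers, tuple(window))
            entry = {"window": list(window), "definition": s_def.to_dict(),
                     "n": len(s_df)}
            entry["MatchMinus"] = _analyze_dataset(
                f"Sens{window}MatchMinus", s_df, STUDY_ADJUSTMENT, COVARIATE_ROSTER
            )
            try:
                _, mr_w, _ = _match_stage(s_df, "study", config)
                entry["MatchPlus"] = _analyze_dataset(
                    f"Sens{window}MatchPlus", _matched_subset(s_df, mr_w),
                    STUDY_ADJUSTMENT, COVARIATE_ROSTER,
                )
                entry["MatchPlus"]["match"] = mr_w
            except (ValueError, SeparationError, ConvergenceError) as e:
                entry["MatchPlus"] = {"not_estimable": True, "reason": str(e)}
            bundle["sensitivity"].append(entry)
    except (KeyError, ValueError, RuntimeError) as e:
        raise StageError(
            f"stage {stage!r} failed with {len(patients)} input patients: {e}"
        ) from e

    bundle["manifest"] = {
        "seed": config.seed,
        "hb_window": list(config.hb_window),
        "caliper_multiplier": config.caliper_multiplier,
        "graymatch_version": __version__,
        "python_version": platform.python_version(),
        "n_input_patients": len(patients),
        "simulated": config.simulate,
        "filters": {
            "base": bundle["definitions"]["base"]["filters"],
            "study": bundle["definitions"]["study"]["filters"],
        },
        "dataset_sizes": {k: v["n"] for k, v in bundle["datasets"].items()},
    }
    return bundle


def effect_comparison_table(bundle: dict) -> pd.DataFrame:
    """One row per dataset: OR, 95% CI, p, n, events (or not-estimable)."""
    rows = []
    for label in FOUR_DATASETS:
        d = bundle["datasets"][label]
        eff = d["effect"]
        crude = d.get("crude", {})
        row = {"dataset": label,
               "crude_odds_ratio": crude.get("odds_ratio", np.nan),
               "crude_ci_low": crude.get("ci_low", np.nan),
               "crude_ci_high": crude.get("ci_high", np.nan)}
        if eff.get("not_estimable"):
            row.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p_value=np.nan, n=d["n"], n_events=0,
                       note="not estimable: " + eff.get("reason", ""))
        else:
            row.update(odds_ratio=eff["odds_ratio"], ci_low=eff["ci_low"],
                       ci_high=eff["ci_high"], p_value=eff["p_value"],
                       n=eff["n"], n_events=eff["n_events"], note="")
        rows.append(row)
    return pd.DataFrame(rows)


def balance_trajectory_table(bundle: dict) -> pd.DataFrame:
    """SMD of every roster covariate across the four datasets (wide)."""
    wide: Optional[pd.DataFrame] = None
    for label in FOUR_DATASETS:
        bt = bundle["datasets"][label]["balance"][["variable", "smd_percent"]]
        bt = bt.rename(columns={"smd_percent": label})
        wide = bt if wide is None else wide.merge(bt, on="variable", how="outer")
    return wide


def generate_report(bundle: dict, outdir: Union[str, Path]) -> Path:
    """Write the report directory: manifest.json, per-dataset CSVs, report.md."""
    missing = [k for k in FOUR_DATASETS if k not in bundle.get("datasets", {})]
    if missing or "manifest" not in bundle:
        raise ValueError(f"incomplete bundle; missing stages: {missing or ['manifest']}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    (outdir / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))
    effects = effect_comparison_table(bundle)
    effects.to_csv(outdir / "effects.csv", index=False)
    trajectory = balance_trajectory_table(bundle)
    trajectory.to_csv(outdir / "balance_trajectory.csv", index=False)
    for label in FOUR_DATASETS:
        d = bundle["datasets"][label]
        d["balance"].to_csv(outdir / f"balance_{label}.csv", index=False)
        d["descriptive"].to_csv(outdir / f"descriptive_{label}.csv", index=False)
        d["members"].to_csv(outdir / f"members_{label}.csv", index=False)
        if "match" in d:
            d["match"].pairs.to_csv(outdir / f"matches_{label}.csv", index=False)
            (outdir / f"match_{label}.json").write_text(
                json.dumps(d["match"].to_dict(), indent=2)
            )

    lines = ["# Transfusion-outcome analysis report", ""]
    lines += ["## Effect comparison across datasets", "",
              effects.round(4).to_markdown(index=False), ""]
    lines += ["## Covariate balance trajectory (SMD, %)", "",
              trajectory.round(2).to_markdown(index=False), ""]
    lines += ["## Cohort flow", ""]
    for pop in ("base", "study"):
        defn = bundle["definitions"][pop]
        lines.append(f"- **{pop}**: {defn['n_input']} in, {defn['n_retained']} retained; "
                     + "; ".join(f"{f['name']}: -{f['excluded']}" for f in defn["filters"]))
    for entry in bundle.get("sensitivity", []):
        eff = entry.get("MatchMinus", {}).get("effect", {})
        or_txt = ("not estimable" if eff.get("not_estimable")
                  else f"OR {eff.get('odds_ratio', float('nan')):.2f}")
        lines.append(f"- sensitivity window {entry['window']}: n={entry['n']}, {or_txt}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
    return outdir
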