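"""Shared test utilities: independent oracles and a lean end-to-end replicate."""

from __future__ import annotations

import numpy as np
import pandas as pd

from graymatch import (
    PropensityModelSpec,
    STUDY_ADJUSTMENT,
    build_base_population,
    build_study_population,
    define_composite_outcome,
    extract_triggers,
    fit_outcome_model,
    fit_propensity,
    match,
    simulate_cohort,
)
from graymatch.config import SimulationConfig


def greedy_match_oracle(scores, exposure, caliper, seed):
    """Independent brute-force greedy matcher: seeded random exposed order,
    full scan of remaining controls, distance ties to smallest control id."""
    scores = np.asarray(scores, dtype=float)
    exposed = [i for i in range(len(scores)) if exposure[i] == 1]
    controls = {i for i in range(len(scores)) if exposure[i] == 0}
    order = np.random.default_rng(seed).permutation(len(exposed))
    pairs = []
    for k in order:
        i = exposed[k]
        best, best_d = None, None
        for j in sorted(controls):
            d = abs(scores[j] - scores[i])
            if d <= caliper and (best_d is None or d < best_d):
                best, best_d = j, d
        if best is not None:
            controls.remove(best)
            pairs.append((i, best, best_d))
    return pairs


def crude_2x2(patients: pd.DataFrame, outcome_col: str = "composite_outcome"):
    """Direct tabulation of the exposure x outcome 2x2 table."""
    t = patients["transfused"].astype(int)
    y = patients[outcome_col].astype(int)
    a = int(((t == 1) & (y == 1)).sum())
    b = int(((t == 1) & (y == 0)).sum())
    c = int(((t == 0) & (y == 1)).sum())
    d = int(((t == 0) & (y == 0)).sum())
    return a, b, c, d


def expand_2x2(a, b, c, d, rng=None):
    """Row-level dataset matching a 2x2 table (exposure, outcome columns)."""
    exposure = np.r_[np.ones(a + b), np.zeros(c + d)].astype(int)
    outcome = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)].astype(int)
    return pd.DataFrame({"patient_id": np.arange(a + b + c + d),
                         "transfused": exposure, "y": outcome})


def run_design(seed: int, n: int = 6000, **config_overrides):
    """Simulate one cohort and run it through base -> study -> match.

    Returns a dict with the intermediate populations, the match result and
    the matched study dataset; used by property tests that do not need the
    full report bundle.
    """
    cfg = SimulationConfig(n_patients=n, seed=seed, **config_overrides)
    patients, hb, tx, truth = simulate_cohort(cfg)
    patients["composite_outcome"] = define_composite_outcome(patients)
    base, base_def = build_base_population(patients)
    triggers = extract_triggers(
        hb[hb["patient_id"].isin(base["patient_id"])],
        tx[tx["patient_id"].isin(base["patient_id"])],
    )
    study, study_def = build_study_population(base, triggers)
    scores, _ = fit_propensity(study, PropensityModelSpec.for_population("study"))
    sub = study[study["patient_id"].isin(scores.index)]
    mr = match(
        scores.loc[sub["patient_id"]].to_numpy(),
        sub["transfused"].to_numpy(),
        ids=sub["patient_id"].to_numpy(),
        seed=seed,
    )
    keep = set(mr.pairs["exposed_id"]) | set(mr.pairs["control_id"])
    matched = study[study["patient_id"].isin(keep)]
    return {
        "patients": patients, "hb": hb, "tx": tx, "truth": truth,
        "base": base, "base_def": base_def, "triggers": triggers,
        "study": study, "study_def": study_def,
        "match": mr, "study_matched": matched,
    }


def study_match_plus_estimate(seed: int, n: int = 6000):
    """Adjusted Study Match+ odds ratio from one simulated replicate."""
    r = run_design(seed, n)
    return fit_outcome_model(
        r["study_matched"], "composite_outcome",
        covariates=STUDY_ADJUSTMENT, label="StudyMatchPlus",
    )
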