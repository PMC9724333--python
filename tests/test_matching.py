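"""Propensity estimation and greedy caliper matching."""

import numpy as np
import pandas as pd
import pytest

from graymatch import (
    PropensityModelSpec,
    SeparationError,
    balance_table,
    fit_propensity,
    match,
)
from helpers import greedy_match_oracle, run_design


def make_dataset(exposure, **cols):
    df = pd.DataFrame({"transfused": exposure, **cols})
    df.insert(0, "patient_id", np.arange(len(df)))
    return df


class TestFitPropensity:
    def test_saturated_single_binary_covariate(self):
        # strata: x=0 -> 10 exposed / 40 controls, x=1 -> 40 / 10
        x = [0] * 50 + [1] * 50
        e = [1] * 10 + [0] * 40 + [1] * 40 + [0] * 10
        df = make_dataset(e, x=x)
        spec = PropensityModelSpec(population="toy", covariates=["x"])
        scores, spec = fit_propensity(df, spec)
        vals = np.unique(np.round(scores.to_numpy(), 6))
        assert vals == pytest.approx([0.2, 0.8], abs=1e-4)
        assert spec.converged

    def test_null_covariates_give_constant_scores(self):
        rng = np.random.default_rng(0)
        df = make_dataset(rng.integers(0, 2, 4000), x=rng.normal(size=4000))
        scores, _ = fit_propensity(
            df, PropensityModelSpec(population="toy", covariates=["x"])
        )
        prev = df["transfused"].mean()
        assert scores.mean() == pytest.approx(prev, abs=0.01)
        assert scores.std() < 0.05

    def test_exposed_scores_dominate_controls_on_confounded_cohort(self, default_cohort):
        patients, _, _, _ = default_cohort
        scores, _ = fit_propensity(patients, PropensityModelSpec.for_population("base"))
        e = patients.set_index("patient_id").loc[scores.index, "transfused"]
        assert scores[e == 1].median() > scores[e == 0].median()
        assert scores[e == 1].mean() > 2 * scores[e == 0].mean()

    def test_perfect_separation_raises(self):
        df = make_dataset([1, 1, 1, 0, 0, 0], x=[5.0, 6.0, 7.0, 1.0, 2.0, 3.0])
        with pytest.raises(SeparationError):
            fit_propensity(df, PropensityModelSpec(population="toy", covariates=["x"]))

    def test_incomplete_cases_dropped_and_counted(self):
        rng = np.random.default_rng(1)
        df = make_dataset(rng.integers(0, 2, 200), x=rng.normal(size=200))
        df.loc[:9, "x"] = np.nan
        _, spec = fit_propensity(
            df, PropensityModelSpec(population="toy", covariates=["x"])
        )
        assert spec.n_dropped_incomplete == 10
        assert spec.n_used == 190

    def test_default_covariate_sets(self):
        assert "bleeding_ge500ml" in PropensityModelSpec.for_population("base").covariates
        assert "bleeding_ge500ml" not in PropensityModelSpec.for_population("study").covariates


class TestMatch:
    def test_unique_nearest_within_caliper(self):
        mr = match([0.50, 0.49, 0.60], [1, 0, 0], caliper=0.05, seed=0)
        assert mr.pairs[["exposed_id", "control_id"]].values.tolist() == [[0, 1]]
        assert mr.matching_rate_exposed == 100.0

    def test_caliper_excludes_distant_pair(self):
        mr = match([0.9, 0.1], [1, 0], caliper=0.05, seed=0)
        assert mr.n_pairs == 0
        assert mr.matching_rate_exposed == 0.0
        assert mr.matching_rate_control == 0.0

    def test_identical_equal_size_groups_match_fully(self):
        s = [0.2, 0.4, 0.6, 0.2, 0.4, 0.6]
        mr = match(s, [1, 1, 1, 0, 0, 0], seed=3)
        assert mr.matching_rate_exposed == 100.0
        assert mr.matching_rate_control == 100.0
        assert (mr.pairs["distance"] == 0).all()

    def test_tie_breaks_to_smallest_control_id(self):
        mr = match([0.5, 0.45, 0.55], [1, 0, 0], caliper=0.2, seed=0)
        assert mr.pairs.loc[0, "control_id"] == 1

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="exposed and a control"):
            match([0.5, 0.6], [1, 1], seed=0)

    def test_deterministic_given_seed_and_order_options(self):
        rng = np.random.default_rng(7)
        s = rng.random(200)
        e = rng.integers(0, 2, 200)
        a = match(s, e, seed=5)
        b = match(s, e, seed=5)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)
        c = match(s, e, seed=5, order="descending")
        assert set(c.pairs.columns) == {"exposed_id", "control_id", "distance"}
        with pytest.raises(ValueError, match="order"):
            match(s, e, seed=5, order="sideways")

    def test_logit_scale_caliper_option(self):
        rng = np.random.default_rng(9)
        s = rng.uniform(0.05, 0.95, 100)
        e = rng.integers(0, 2, 100)
        mr = match(s, e, seed=1, caliper_on_logit=True)
        assert mr.caliper == pytest.approx(
            0.2 * np.std(np.log(s / (1 - s)), ddof=1)
        )

    @pytest.mark.parametrize("trial", range(20))
    def test_agrees_with_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(10, 500))
        s = rng.random(n)
        e = np.zeros(n, dtype=int)
        e[rng.choice(n, size=max(1, n // 4), replace=False)] = 1
        if e.sum() == n:
            e[0] = 0
        caliper = float(rng.uniform(0.01, 0.3))
        mr = match(s, e, caliper=caliper, seed=trial)
        # oracle permutes exposed positions exactly as match() does
        oracle = greedy_match_oracle(s, e, caliper, seed=trial)
        got = sorted(map(tuple, mr.pairs[["exposed_id", "control_id"]].values))
        exp = sorted((i, j) for i, j, _ in oracle)
        assert got == exp
        # invariants: one-to-one and within caliper
        assert mr.pairs["exposed_id"].is_unique
        assert mr.pairs["control_id"].is_unique
        assert (mr.pairs["distance"] <= caliper + 1e-12).all()

    def test_matching_reduces_propensity_score_imbalance(self, default_cohort):
        patients, _, _, _ = default_cohort
        scores, _ = fit_propensity(patients, PropensityModelSpec.for_population("base"))
        sub = patients[patients["patient_id"].isin(scores.index)].copy()
        sub["ps"] = scores.loc[sub["patient_id"]].to_numpy()
        mr = match(sub["ps"].to_numpy(), sub["transfused"].to_numpy(),
                   ids=sub["patient_id"].to_numpy(), seed=0)
        before = balance_table(sub, {"ps": "continuous"}).loc[0, "smd_percent"]
        keep = set(mr.pairs["exposed_id"]) | set(mr.pairs["control_id"])
        after = balance_table(sub[sub["patient_id"].isin(keep)],
                              {"ps": "continuous"}).loc[0, "smd_percent"]
        assert after <= before
        assert after < 10
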