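"""Population filters, trigger extraction, outcomes, descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from graymatch import (
    build_base_population,
    build_study_population,
    define_composite_outcome,
    descriptive_summary,
    extract_trigger_value,
    extract_triggers,
)
from graymatch.cohort import SchemaError


def toy_patients(**overrides):
    df = pd.DataFrame({
        "patient_id": range(5),
        "major_surgery": [1, 1, 1, 1, 1],
        "stay_hours": [48.0, 10.0, 30.0, 100.0, 72.0],
        "high_altitude": [0, 0, 0, 0, 0],
        "bleeding_ge500ml": [0, 0, 0, 0, 0],
    })
    for k, v in overrides.items():
        df[k] = v
    return df


class TestBasePopulation:
    def test_stay_filter_counts(self):
        base, cd = build_base_population(toy_patients())
        assert len(base) == 4
        assert dict(cd.filters)["stay_lt_24h"] == 1
        assert cd.n_input == 5 and cd.n_retained == 4

    def test_high_altitude_excluded(self):
        base, cd = build_base_population(toy_patients(high_altitude=[1, 0, 0, 0, 0]))
        assert 0 not in base["patient_id"].values
        assert dict(cd.filters)["high_altitude_residence"] == 1

    def test_non_major_surgery_excluded(self):
        base, cd = build_base_population(toy_patients(major_surgery=[0, 1, 1, 1, 1]))
        assert dict(cd.filters)["not_major_surgery"] == 1

    def test_empty_table(self):
        base, cd = build_base_population(toy_patients().iloc[:0])
        assert len(base) == 0
        assert all(c == 0 for _, c in cd.filters)

    def test_missing_columns_schema_error(self):
        with pytest.raises(SchemaError, match="stay_hours"):
            build_base_population(pd.DataFrame({"patient_id": [1]}))

    def test_filter_accounting_sums(self):
        df = toy_patients(major_surgery=[0, 1, 1, 1, 1], high_altitude=[0, 0, 1, 0, 0])
        base, cd = build_base_population(df)
        assert sum(c for _, c in cd.filters) + len(base) == len(df)


def series(vals, pid=7):
    return pd.DataFrame({"patient_id": pid, "occasion": range(len(vals)), "hb_gdl": vals})


def events(occasions, pid=7):
    return pd.DataFrame({"patient_id": pid, "occasion": occasions})


class TestTriggerValue:
    def test_last_measurement_before_initial_transfusion(self):
        tv = extract_trigger_value(series([13.0, 8.9, 9.4]), events([1.5]))
        assert tv.value == 8.9
        assert tv.source == "last_pre_transfusion"
        assert tv.occasion_index == 1

    def test_nadir_for_controls(self):
        tv = extract_trigger_value(series([12.1, 9.2, 10.4]), events([]))
        assert tv.value == 9.2
        assert tv.source == "stay_nadir"

    def test_transfusion_before_any_measurement_unresolvable(self):
        assert extract_trigger_value(series([12.0, 11.0]), events([-0.5])) is None

    def test_no_measurements_errors(self):
        with pytest.raises(ValueError, match="no hemoglobin"):
            extract_trigger_value(series([]), events([]))

    def test_multiple_transfusions_use_first(self):
        tv = extract_trigger_value(series([12.0, 9.0, 8.0, 9.5]), events([1.5, 2.5]))
        assert tv.value == 9.0

    def test_vectorized_matches_scalar_oracle(self):
        """extract_triggers agrees with the per-patient exhaustive scan on
        random toy series."""
        rng = np.random.default_rng(42)
        hb_rows, tx_rows = [], []
        for pid in range(200):
            k = rng.integers(1, 6)
            vals = np.round(rng.uniform(5, 15, k), 2)
            hb_rows.append(series(vals, pid))
            if rng.random() < 0.5:
                tx_rows.append(events([float(rng.integers(0, k + 1)) - 0.5], pid))
        hb = pd.concat(hb_rows, ignore_index=True)
        tx = (pd.concat(tx_rows, ignore_index=True) if tx_rows
              else pd.DataFrame(columns=["patient_id", "occasion"]))
        out = extract_triggers(hb, tx).set_index("patient_id")
        for pid in range(200):
            expected = extract_trigger_value(
                hb[hb.patient_id == pid], tx[tx.patient_id == pid]
            )
            row = out.loc[pid]
            if expected is None:
                assert row["unresolvable"]
            else:
                assert row["trigger_value"] == pytest.approx(expected.value)
                assert row["source"] == expected.source


def triggers_frame(values, sources=None, unresolvable=None):
    n = len(values)
    return pd.DataFrame({
        "patient_id": range(n),
        "trigger_value": values,
        "source": sources or ["stay_nadir"] * n,
        "unresolvable": unresolvable or [False] * n,
    })


class TestStudyPopulation:
    def test_window_bounds_inclusive(self):
        base = toy_patients()
        trig = triggers_frame([7.5, 9.5, 7.49, 9.51, 8.0])
        study, cd = build_study_population(base, trig)
        assert set(study["patient_id"]) == {0, 1, 4}
        assert dict(cd.filters)["trigger_outside_window"] == 2

    def test_transfused_trigger_above_window_excluded(self):
        # transfusion at hemoglobin >= 10 g/dL is beyond the clinical standard
        base = toy_patients()
        trig = triggers_frame([10.2, 8.0, 8.0, 8.0, 8.0],
                              sources=["last_pre_transfusion"] + ["stay_nadir"] * 4)
        study, _ = build_study_population(base, trig)
        assert 0 not in study["patient_id"].values

    def test_bleeding_excluded_even_in_window(self):
        base = toy_patients(bleeding_ge500ml=[1, 0, 0, 0, 0])
        study, cd = build_study_population(base, triggers_frame([8.0] * 5))
        assert 0 not in study["patient_id"].values
        assert dict(cd.filters)["bleeding_ge500ml"] == 1

    def test_unresolvable_counted(self):
        base = toy_patients()
        trig = triggers_frame([8.0] * 5, unresolvable=[True] + [False] * 4)
        study, cd = build_study_population(base, trig)
        assert dict(cd.filters)["trigger_unresolvable"] == 1

    def test_invalid_window(self):
        with pytest.raises(ValueError, match="low < high"):
            build_study_population(toy_patients(), triggers_frame([8.0] * 5),
                                   window=(9.5, 7.5))

    def test_study_subset_of_base_with_consistent_accounting(self):
        base = toy_patients(bleeding_ge500ml=[1, 0, 0, 0, 1])
        trig = triggers_frame([8.0, 12.0, 8.8, 9.0, 8.0])
        study, cd = build_study_population(base, trig)
        assert set(study.patient_id) <= set(base.patient_id)
        assert sum(c for _, c in cd.filters) + len(study) == len(base)


class TestCompositeOutcome:
    def test_death_alone(self):
        df = pd.DataFrame({"death": [1], "ischemic_event": [0],
                           "infection": [0], "other_complication": [0]})
        assert define_composite_outcome(df).tolist() == [1]

    def test_all_clear(self):
        df = pd.DataFrame({"death": [0], "ischemic_event": [0],
                           "infection": [0], "other_complication": [0]})
        assert define_composite_outcome(df).tolist() == [0]

    def test_single_infection_counts(self):
        df = pd.DataFrame({"death": [0, 0], "infection": [1, 0]})
        assert define_composite_outcome(df).tolist() == [1, 0]

    def test_missing_flags_treated_as_false(self):
        df = pd.DataFrame({"death": [np.nan, 1.0], "infection": [0, 0]})
        assert define_composite_outcome(df).tolist() == [0, 1]

    def test_no_outcome_columns_errors(self):
        with pytest.raises(SchemaError):
            define_composite_outcome(pd.DataFrame({"age_years": [70]}))


class TestDescriptiveSummary:
    def test_published_event_rates(self, table1_patients):
        out = descriptive_summary(
            table1_patients, {"complication": "binary", "death": "binary"}
        ).set_index(["variable", "group"])
        assert out.loc[("complication", 1), "percent"] == pytest.approx(15.41, abs=0.01)
        assert out.loc[("complication", 0), "percent"] == pytest.approx(4.12, abs=0.01)
        assert out.loc[("death", 1), "percent"] == pytest.approx(5.89, abs=0.01)
        assert out.loc[("death", 0), "percent"] == pytest.approx(0.53, abs=0.01)

    def test_identical_records_sd_zero(self):
        df = pd.DataFrame({"transfused": [0, 0, 1, 1], "bmi": [22.0] * 4})
        out = descriptive_summary(df, {"bmi": "continuous"})
        assert (out["sd"] == 0).all()

    def test_unknown_variable_errors(self, table1_patients):
        with pytest.raises(KeyError, match="nonexistent"):
            descriptive_summary(table1_patients, {"nonexistent": "binary"})
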