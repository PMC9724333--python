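"""Population construction, trigger-value extraction and outcome definition.

The design proceeds in two restriction steps:

1. *Base population* — major surgery, hospital stay >= 24 h, not residing at
   high altitude (2000-5000 m), emulating the inclusion rules of conventional
   observational transfusion studies.
2. *Study population* — additionally no intraoperative bleeding >= 500 mL and
   a per-patient *trigger value* inside the gray zone of the transfusion
   decision (7.5-9.5 g/dL by default, inclusive at both ends).

The trigger value stands in for the hemoglobin level on which the transfusion
decision was made: the last measurement strictly before the initial
transfusion for transfused patients, the in-stay nadir for controls.  Both
restriction steps keep a per-filter exclusion ledger so the cohort flow can
be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """Input table is missing required columns."""


BASE_REQUIRED_COLUMNS = ["patient_id", "major_surgery", "stay_hours", "high_altitude"]

OUTCOME_COMPONENT_COLUMNS = ["death", "ischemic_event", "infection", "other_complication"]


@dataclass
class TriggerValue:
    """Per-patient hemoglobin value standing in for the transfusion decision."""

    patient_id: int
    value: float
    source: str  # "last_pre_transfusion" | "stay_nadir"
    occasion_index: float


@dataclass
class CohortDefinition:
    """Provenance of a cohort: which filters ran and what each excluded."""

    label: str  # "base" | "study"
    filters: list[tuple[str, int]] = field(default_factory=list)
    hb_window: Optional[tuple[float, float]] = None
    n_input: int = 0
    n_retained: int = 0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "hb_window": list(self.hb_window) if self.hb_window else None,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "filters": [{"name": n, "excluded": c} for n, c in self.filters],
        }


def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"input table is missing required columns: {missing}")


def build_base_population(patients: pd.DataFrame) -> tuple[pd.DataFrame, CohortDefinition]:
    """Apply the base-population inclusion criteria with exclusion accounting.

    Filters, in order: major surgery; hospital stay >= 24 h; not residing at
    2000-5000 m altitude.  Each filter's exclusion count refers to records
    that survived the previous filters.
    """
    _require_columns(patients, BASE_REQUIRED_COLUMNS)
    cd = CohortDefinition(label="base", n_input=len(patients))
    df = patients
    for name, mask_fn in [
        ("not_major_surgery", lambda d: d["major_surgery"].astype(bool)),
        ("stay_lt_24h", lambda d: d["stay_hours"] >= 24),
        ("high_altitude_residence", lambda d: ~d["high_altitude"].astype(bool)),
    ]:
        keep = mask_fn(df)
        cd.filters.append((name, int((~keep).sum())))
        df = df[keep]
    cd.n_retained = len(df)
    return df.reset_index(drop=True), cd


def extract_trigger_value(
    hb: pd.DataFrame, tx: pd.DataFrame
) -> Optional[TriggerValue]:
    """Trigger value for a single patient.

    ``hb`` is this patient's measurements (columns ``occasion``, ``hb_gdl``),
    ``tx`` their transfusion events (column ``occasion``; may be empty).
    Transfused: the measurement at the greatest occasion strictly before the
    first event (ties at one occasion resolve to the minimum value).
    Non-transfused: the minimum over all measurements.  Returns ``None`` for
    a transfused patient with no measurement before the first event
    (unresolvable; excluded and counted downstream).
    """
    if len(hb) == 0:
        raise ValueError("patient has no hemoglobin measurements")
    pid = int(hb["patient_id"].iloc[0]) if "patient_id" in hb.columns else -1
    if len(tx) == 0:
        i = hb["hb_gdl"].idxmin()
        return TriggerValue(pid, float(hb.loc[i, "hb_gdl"]), "stay_nadir",
                            float(hb.loc[i, "occasion"]))
    first_tx = float(tx["occasion"].min())
    before = hb[hb["occasion"] < first_tx]
    if len(before) == 0:
        return None
    last_occ = before["occasion"].max()
    value = float(before.loc[before["occasion"] == last_occ, "hb_gdl"].min())
    return TriggerValue(pid, value, "last_pre_transfusion", float(last_occ))


def extract_triggers(hb: pd.DataFrame, tx: pd.DataFrame) -> pd.DataFrame:
    """Vectorized trigger extraction for a whole cohort.

    Returns one row per patient present in ``hb`` with columns
    ``patient_id, trigger_value, source, occasion_index, unresolvable``.
    Patients whose first transfusion precedes every measurement are flagged
    ``unresolvable`` (trigger NaN).
    """
    _require_columns(hb, ["patient_id", "occasion", "hb_gdl"])
    _require_columns(tx, ["patient_id", "occasion"])
    first_tx = tx.groupby("patient_id")["occasion"].min()

    h = hb[["patient_id", "occasion", "hb_gdl"]].copy()
    h["first_tx"] = h["patient_id"].map(first_tx)
    transfused_ids = first_tx.index

    ctrl = h[h["first_tx"].isna()]
    # nadir: sort by value then take first per patient (stable ties)
    ctrl = ctrl.sort_values(["patient_id", "hb_gdl", "occasion"], kind="stable")
    nadir = ctrl.groupby("patient_id", as_index=False).first()

    exp = h[h["first_tx"].notna() & (h["occasion"] < h["first_tx"])]
    # last pre-transfusion occasion; ties at that occasion -> minimum value
    exp = exp.sort_values(["patient_id", "occasion", "hb_gdl"],
                          ascending=[True, False, True], kind="stable")
    last_pre = exp.groupby("patient_id", as_index=False).first()

    rows = []
    if len(nadir):
        rows.append(pd.DataFrame({
            "patient_id": nadir["patient_id"],
            "trigger_value": nadir["hb_gdl"],
            "source": "stay_nadir",
            "occasion_index": nadir["occasion"].astype(float),
            "unresolvable": False,
        }))
    if len(last_pre):
        rows.append(pd.DataFrame({
            "patient_id": last_pre["patient_id"],
            "trigger_value": last_pre["hb_gdl"],
            "source": "last_pre_transfusion",
            "occasion_index": last_pre["occasion"].astype(float),
            "unresolvable": False,
        }))
    missing = np.setdiff1d(np.asarray(transfused_ids),
                           last_pre["patient_id"].to_numpy() if len(last_pre) else [])
    if missing.size:
        rows.append(pd.DataFrame({
            "patient_id": missing,
            "trigger_value": np.nan,
            "source": "last_pre_transfusion",
            "occasion_index": np.nan,
            "unresolvable": True,
        }))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["patient_id", "trigger_value", "source", "occasion_index", "unresolvable"]
    )
    return out.sort_values("patient_id", ignore_index=True)


def build_study_population(
    base: pd.DataFrame,
    triggers: pd.DataFrame,
    window: tuple[float, float] = (7.5, 9.5),
) -> tuple[pd.DataFrame, CohortDefinition]:
    """Restrict the base population to the stable-hemoglobin study population.

    Filters, in order: unresolvable trigger; intraoperative bleeding
    >= 500 mL; trigger value outside ``window`` (inclusive bounds).  Because
    a trigger >= 10 g/dL falls outside any sub-10 window, transfusions beyond
    the current clinical standard are excluded by construction.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"hemoglobin window must satisfy low < high, got {window}")
    _require_columns(base, ["patient_id", "bleeding_ge500ml"])
    df = base.merge(
        triggers[["patient_id", "trigger_value", "source", "unresolvable"]],
        on="patient_id", how="left",
    )
    cd = CohortDefinition(label="study", hb_window=(lo, hi), n_input=len(df))
    no_trigger = df["unresolvable"].isna() | df["unresolvable"].astype(bool)
    cd.filters.append(("trigger_unresolvable", int(no_trigger.sum())))
    df = df[~no_trigger]
    keep = ~df["bleeding_ge500ml"].astype(bool)
    cd.filters.append(("bleeding_ge500ml", int((~keep).sum())))
    df = df[keep]
    keep = (df["trigger_value"] >= lo) & (df["trigger_value"] <= hi)
    cd.filters.append(("trigger_outside_window", int((~keep).sum())))
    df = df[keep]
    cd.n_retained = len(df)
    return df.reset_index(drop=True), cd


def define_composite_outcome(patients: pd.DataFrame) -> pd.Series:
    """Death or any in-hospital complication, as one binary endpoint.

    Complication groups: ischemic events, infections, and other
    complications.  Missing component flags count as absent.
    """
    present = [c for c in OUTCOME_COMPONENT_COLUMNS if c in patients.columns]
    if not present:
        raise SchemaError(
            f"no outcome component columns found; expected any of {OUTCOME_COMPONENT_COLUMNS}"
        )
    out = patients[present].fillna(0).astype(int).max(axis=1).astype(np.int8)
    out.name = "composite_outcome"
    return out


def descriptive_summary(
    dataset: pd.DataFrame,
    variables: dict[str, str],
    exposure_col: str = "transfused",
) -> pd.DataFrame:
    """Per-exposure-group descriptive table.

    ``variables`` maps column name to ``"binary"`` or ``"continuous"``.
    Binary variables report n and percent; continuous report mean and SD
    (ddof=1).  Output is long format: one row per variable per group.
    """
    unknown = [v for v in variables if v not in dataset.columns]
    if unknown:
        raise KeyError(f"unknown variables: {unknown}")
    rows = []
    for gval, g in dataset.groupby(dataset[exposure_col].astype(int)):
        for name, kind in variables.items():
            col = g[name].dropna()
            if kind == "binary":
                count = int(col.astype(int).sum())
                rows.append({
                    "variable": name, "group": gval, "n": len(g),
                    "count": count,
                    "percent": 100.0 * count / len(col) if len(col) else np.nan,
                    "mean": np.nan, "sd": np.nan,
                })
            elif kind == "continuous":
                rows.append({
                    "variable": name, "group": gval, "n": len(g),
                    "count": np.nan, "percent": np.nan,
                    "mean": float(col.mean()) if len(col) else np.nan,
                    "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
                })
            else:
                raise ValueError(f"variable {name!r}: unknown kind {kind!r}")
    return pd.DataFrame(rows)
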