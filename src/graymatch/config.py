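"""Configuration objects for simulation and pipeline runs.

Both configs are pydantic models so that invalid fields fail loudly with the
offending field named, and so that a run can be reproduced from a YAML/JSON
file alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: Measurement occasions, in order: hospital admission, immediately pre-op,
#: then post-operative days 1..k.  Time is discrete; transfusion events fall
#: strictly between two occasions (index j + 0.5).
DEFAULT_SCHEDULE = ["admission", "preop", "pod1", "pod2", "pod3"]

#: Marginal probabilities of the binary baseline covariates, calibrated to the
#: non-transfused column of the multicenter perioperative cohort this
#: generator emulates (male ~52%, ASA>=3 ~23%, operation >=3h ~21%, ICU ~8%,
#: intraoperative bleeding >=500 mL ~2%).
DEFAULT_MARGINS = {
    "male": 0.52,
    "smoking": 0.10,
    "hypertension": 0.50,
    "coronary_heart_disease": 0.103,
    "diabetes": 0.126,
    "stroke": 0.015,
    "copd": 0.010,
    "asa_ge3": 0.23,
    "albumin_lt35": 0.14,
    "high_creatinine": 0.098,
    "wbc_gt10": 0.09,
    "operation_time_ge3h": 0.22,
    "major_surgery": 0.97,
    "high_altitude": 0.01,
}


class SimulationConfig(BaseModel):
    """Parameters of the synthetic perioperative cohort generator.

    The generator reproduces the confounding-by-indication structure of
    transfusion practice: anemia, bleeding, poor physical status and long
    operations drive both the transfusion decision and the composite adverse
    outcome, so a naive comparison of transfused vs. non-transfused patients
    is biased even when ``true_transfusion_log_or`` is 0.
    """

    n_patients: int = Field(6000, ge=2)
    seed: int = 0
    #: causal log odds ratio of transfusion on the composite outcome
    true_transfusion_log_or: float = 0.0
    #: multiplier on the anemia / bleeding / ASA coefficients in the outcome
    #: model; 0 switches confounding off entirely
    confounding_strength: float = Field(1.0, ge=0.0)
    #: marginal probability of ever being transfused during the stay
    target_transfusion_rate: float = Field(0.108, gt=0.0, lt=1.0)
    #: marginal probability of the composite outcome (death or any in-hospital
    #: complication)
    target_outcome_rate: float = Field(0.057, gt=0.0, lt=1.0)
    covariate_margins: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_MARGINS)
    )
    hb_preop_mean: float = Field(13.5, gt=0.0)
    hb_preop_sd: float = Field(1.8, gt=0.0)
    #: probability of intraoperative bleeding >=500 mL given operation >=3 h
    bleed_prob_given_long_op: float = Field(0.15, ge=0.0, le=1.0)
    #: same, for shorter operations
    bleed_prob_given_short_op: float = Field(0.012, ge=0.0, le=1.0)
    #: mean extra post-operative hemoglobin drop attributable to mass
    #: bleeding, g/dL
    hb_drop_per_bleed: float = Field(3.0, ge=0.0)
    #: hemoglobin rise per transfusion episode applied to all subsequent
    #: measurements, g/dL
    transfusion_hb_gain: float = Field(1.0, ge=0.0)
    measurement_schedule: list[str] = Field(
        default_factory=lambda: list(DEFAULT_SCHEDULE)
    )
    #: fraction of operation-time values set to missing, to exercise
    #: complete-case handling downstream (off by default)
    missing_operation_time_rate: float = Field(0.0, ge=0.0, le=0.07)

    @field_validator("covariate_margins")
    @classmethod
    def _margins_are_probabilities(cls, v: dict[str, float]) -> dict[str, float]:
        for name, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"covariate_margins[{name!r}] must be in [0, 1], got {p}"
                )
        return v

    @field_validator("measurement_schedule")
    @classmethod
    def _schedule_nonempty(cls, v: list[str]) -> list[str]:
        if len(v) < 3:
            raise ValueError(
                "measurement_schedule needs admission, preop and at least one "
                f"post-operative occasion; got {v}"
            )
        return v

    def to_file(self, path: Union[str, Path]) -> None:
        path = Path(path)
        data = self.model_dump(mode="json")
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.model_validate(data)


class RunConfig(BaseModel):
    """Configuration of a full four-dataset analysis run.

    Either point ``patients_csv``/``hemoglobin_csv``/``transfusions_csv`` at
    existing input files, or set ``simulate=True`` to generate a synthetic
    cohort from ``simulation`` first.
    """

    simulate: bool = True
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    patients_csv: Optional[str] = None
    hemoglobin_csv: Optional[str] = None
    transfusions_csv: Optional[str] = None
    #: the gray zone of the transfusion decision, g/dL, inclusive bounds
    hb_window: tuple[float, float] = (7.5, 9.5)
    #: additional windows analyzed as sensitivity analyses
    sensitivity_windows: list[tuple[float, float]] = Field(
        default_factory=lambda: [(8.0, 10.0)]
    )
    caliper_multiplier: float = Field(0.2, gt=0.0)
    #: caliper on the raw probability scale by default; set True for the
    #: common logit-scale convention
    caliper_on_logit: bool = False
    match_order: str = "random"
    conditional_matched_model: bool = False
    seed: int = 0
    output_dir: str = "graymatch_output"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        for w in [self.hb_window, *self.sensitivity_windows]:
            lo, hi = w
            if not lo < hi:
                raise ValueError(f"hemoglobin window must satisfy low < high, got {w}")
        if not self.simulate:
            for field in ("patients_csv", "hemoglobin_csv", "transfusions_csv"):
                p = getattr(self, field)
                if p is None:
                    raise ValueError(f"{field} is required when simulate=False")
                if not Path(p).exists():
                    raise ValueError(f"{field}: file not found: {p}")
        if self.match_order not in {"random", "descending"}:
            raise ValueError(f"match_order must be 'random' or 'descending', got {self.match_order!r}")
        return self

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.model_validate(data)

    def to_file(self, path: Union[str, Path]) -> None:
        path = Path(path)
        data = self.model_dump(mode="json")
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))
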