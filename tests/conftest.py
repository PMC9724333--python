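import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from graymatch import SimulationConfig, define_composite_outcome, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=6000) shared across tests."""
    patients, hb, tx, truth = simulate_cohort(SimulationConfig(n_patients=6000, seed=3))
    patients = patients.copy()
    patients["composite_outcome"] = define_composite_outcome(patients)
    return patients, hb, tx, truth


@pytest.fixture(scope="session")
def table1_patients():
    """Base-population fixture reproducing the published baseline table's
    event counts: 6141 patients, 662 transfused; 102/39 complications/deaths
    among transfused, 226/29 among controls."""
    def block(n, n_compl, n_death):
        df = pd.DataFrame({
            "complication": np.zeros(n, dtype=int),
            "death": np.zeros(n, dtype=int),
        })
        df.loc[: n_compl - 1, "complication"] = 1
        df.loc[: n_death - 1, "death"] = 1
        return df

    exposed = block(662, 102, 39)
    exposed["transfused"] = 1
    control = block(5479, 226, 29)
    control["transfused"] = 0
    df = pd.concat([exposed, control], ignore_index=True)
    df.insert(0, "patient_id", np.arange(len(df)))
    return df
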