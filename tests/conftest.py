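import numpy as np
import pandas as pd
import pytest

from mirisk.cohort import CohortTable
from mirisk.quantification import CtPanel, impute_undetermined
from mirisk.synthetic import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic cohort shared across tests (read-only)."""
    params = SimulationParams(n_per_group=16, seed=11)
    return simulate_cohort(params)


@pytest.fixture
def tiny_panel():
    """Hand-built 4-miRNA × 4-sample Ct panel with one undetermined well."""
    ct = pd.DataFrame(
        {
            "s1": [30.0, 28.0, 25.0, np.nan],
            "s2": [31.0, 29.0, 26.0, 39.0],
            "s3": [30.5, 28.5, 25.5, 38.0],
            "s4": [29.5, 27.5, 24.5, 37.0],
        },
        index=["ref1", "ref2", "target", "sparse"],
    )
    return CtPanel(ct=ct)


@pytest.fixture
def tiny_cohort():
    df = pd.DataFrame(
        {
            "group": [0, 0, 1, 1],
            "absorbance_415": [0.19, 0.25, 0.05, 0.20],
            "age": [66.0, 70.0, 72.0, 68.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return CohortTable(df)


@pytest.fixture
def imputed(tiny_panel):
    return impute_undetermined(tiny_panel)
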