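import numpy as np
import pandas as pd
import pytest

from metalage import (
    SimulationConfig,
    attach_aging_markers,
    generate_cohort,
)
from metalage.exposure import creatinine_correct, design_matrix


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Default-condition cohort, small enough for fast unit tests."""
    return generate_cohort(SimulationConfig(n_participants=800, seed=42))


@pytest.fixture(scope="session")
def scored_cohort() -> pd.DataFrame:
    """Mid-size cohort with aging markers attached (shared across tests)."""
    cohort = generate_cohort(SimulationConfig(n_participants=4000, seed=7))
    return attach_aging_markers(cohort)


@pytest.fixture(scope="session")
def scored_design(scored_cohort):
    """Covariate design matrix matched to the scored cohort."""
    return design_matrix(scored_cohort)


@pytest.fixture(scope="session")
def metals_ugg(scored_cohort) -> pd.DataFrame:
    """Creatinine-corrected metal exposures (ug/g) for the scored cohort."""
    creat = scored_cohort["creatinine_mgdl"].to_numpy()
    from metalage.cohort import METALS
    return pd.DataFrame(
        {m: creatinine_correct(scored_cohort[f"metal_{m}"].to_numpy(), creat)
         for m in METALS})
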