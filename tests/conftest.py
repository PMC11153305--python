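import numpy as np
import pandas as pd
import pytest

from glycotrial.drugs import DrugSpec, DrugTable
from glycotrial import examples
from glycotrial.simulate import SimulationConfig, cohort_from_counts, simulate_cohort


@pytest.fixture(scope="session")
def drug_table() -> DrugTable:
    return DrugTable(
        [
            DrugSpec(name="metformin", drug_class="biguanide", max_daily_dose=3000, adjustment_factor=1.5),
            DrugSpec(name="gliclazide", drug_class="sulfonylurea", max_daily_dose=240, adjustment_factor=1.5),
            DrugSpec(name="sitagliptin", drug_class="DPP4 inhibitor", max_daily_dose=100, adjustment_factor=0.75),
        ]
    )


@pytest.fixture(scope="session")
def itt_cohort() -> pd.DataFrame:
    """Cohort encoding the published 12-month ITT category counts."""
    return cohort_from_counts(examples.ITT_12M)


@pytest.fixture(scope="session")
def pp_cohort() -> pd.DataFrame:
    """Cohort encoding the published 12-month per-protocol category counts."""
    return cohort_from_counts(examples.PP_12M, compliant=True)


@pytest.fixture(scope="session")
def small_simulated_cohort() -> pd.DataFrame:
    cfg = SimulationConfig(n_participants=60)
    return simulate_cohort(cfg, seed=424242)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
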