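import numpy as np
import pytest

from clearmark.cohort import CohortConfig, HazardConfig, simulate_cohort
from clearmark.params import default_pop_params
from clearmark.pk import DoseEvent, IndividualPKParams


@pytest.fixture(scope="session")
def pop():
    return default_pop_params()


@pytest.fixture(scope="session")
def typical_patient(pop):
    """Population-typical individual at a 55 kg lean body weight."""
    return IndividualPKParams.from_population(pop, 55.0)


@pytest.fixture(scope="session")
def single_dose():
    return [DoseEvent(0.0, 200.0)]


@pytest.fixture(scope="session")
def small_cohort(pop):
    """40 patients under the default study-like design (shared, read-only)."""
    return simulate_cohort(CohortConfig(n=40), seed=123, pop=pop)


@pytest.fixture()
def hazard_config():
    return HazardConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250924)
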