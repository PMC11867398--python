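import numpy as np
import pytest

from leadchel.cohort import CohortSpec, generate_cohort
from leadchel.model import ModelInputs, fit_survival_inputs
from leadchel.sensitivity import run_psa
from leadchel.strategy import StrategySpec


@pytest.fixture(scope="session")
def cohort_df():
    """Synthetic reference cohort (n=670, fixed seed)."""
    return generate_cohort(CohortSpec(seed=20240901))


@pytest.fixture(scope="session")
def survival_inputs(cohort_df):
    surv, _ = fit_survival_inputs(cohort_df)
    return surv


@pytest.fixture(scope="session")
def model_inputs(survival_inputs):
    return ModelInputs(survival=survival_inputs)


@pytest.fixture(scope="session")
def base_strategy():
    return StrategySpec()


@pytest.fixture(scope="session")
def psa_small(model_inputs, base_strategy):
    """A modest PSA sample shared across CEAC / VOI tests."""
    return run_psa(model_inputs, base_strategy, n_iter=500, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
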