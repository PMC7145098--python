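import numpy as np
import pandas as pd
import pytest

from bflact.population import PopulationParams, sample_cohort

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def params() -> PopulationParams:
    return PopulationParams()


@pytest.fixture(scope="session")
def cohort_small(params) -> pd.DataFrame:
    """A small fixed cohort for fast structural tests."""
    return sample_cohort(500, params, seed=1234)


@pytest.fixture(scope="session")
def cohort_large(params) -> pd.DataFrame:
    """A large fixed cohort for marginal-convergence checks."""
    return sample_cohort(50_000, params, seed=99)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
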