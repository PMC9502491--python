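import numpy as np
import pytest

from nebpk.population import default_population_model, generate_dataset
from nebpk.structural import PKParams


@pytest.fixture(scope="session")
def final_params() -> PKParams:
    """The final-model population estimates used throughout the tests."""
    return PKParams(tlag=0.30, ka=2.06, cl=0.22, v1=4.21, q=0.59, v2=7.12)


@pytest.fixture(scope="session")
def popmodel():
    return default_population_model()


@pytest.fixture(scope="session")
def study_dataset():
    """One simulated 30-subject study at the default conditions (seed 42)."""
    return generate_dataset(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
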