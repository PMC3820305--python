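import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stemdiff.simulate import PopulationConfig, simulate_population

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def wt_population() -> pd.DataFrame:
    """Medium wild-type population with default truth parameters."""
    return simulate_population(PopulationConfig(n_cells=2000, seed=11))


@pytest.fixture(scope="session")
def stat3b_population() -> pd.DataFrame:
    return simulate_population(
        PopulationConfig(n_cells=2000, seed=11, condition="stat3b")
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
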