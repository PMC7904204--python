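import numpy as np
import pandas as pd
import pytest

from healthineq import SimulationConfig, generate_population, make_lms_fixture


@pytest.fixture(scope="session")
def lms_fixture() -> pd.DataFrame:
    return make_lms_fixture()


@pytest.fixture(scope="session")
def small_population() -> pd.DataFrame:
    """A 4,000-record population reused by read-only tests."""
    df = generate_population(SimulationConfig(n=4000, seed=11))
    return df.assign(wealth_quintile=df["wealth_quintile"].astype(str))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
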