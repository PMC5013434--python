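import numpy as np
import pandas as pd
import pytest

from clinexp.io import CountMatrix
from clinexp.simulate import SimulationConfig, simulate_counts, simulate_design


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_transcripts=400, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    counts, truth = simulate_counts(small_config)
    meta = simulate_design(small_config)
    return counts, truth, meta


@pytest.fixture(scope="session")
def latitudes() -> np.ndarray:
    return np.repeat(np.array([39.5, 43.8, 47.5, 51.2, 55.5, 59.8]), 3)


@pytest.fixture()
def toy_counts() -> CountMatrix:
    df = pd.DataFrame(
        {"s1": [10, 0, 500], "s2": [20, 1, 1000], "s3": [30, 0, 1500]},
        index=["t1", "t2", "t3"],
    )
    return CountMatrix(df)
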