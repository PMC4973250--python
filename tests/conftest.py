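import numpy as np
import pytest

from repeatburst import (
    ModelParams,
    SimConfig,
    estimate_T1,
    simulate_burst,
)


@pytest.fixture(scope="session")
def alu_like_params() -> ModelParams:
    """Standard study conditions: delta*gamma = 200 mu0, Alu-like element."""
    base = ModelParams(gamma=200.0, delta=1.0)
    T1 = estimate_T1(10_000, base)
    return ModelParams(gamma=200.0, delta=1.0, T1=T1, T2=0.024)


@pytest.fixture(scope="session")
def small_tree():
    """A finalized 50-leaf burst used by structural tests."""
    params = ModelParams(gamma=10.0, delta=0.5, T1=0.5, T2=0.2)
    return simulate_burst(SimConfig(params=params, target_n=50, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
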