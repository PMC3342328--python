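import numpy as np
import pytest

from tissueratchet import ModelParams


@pytest.fixture
def base_params() -> ModelParams:
    """Reference parameter set used throughout: valid regime, beta = 2."""
    return ModelParams(n_cells=5000, r0=0.9, delta=0.05, apoptosis_prob=0.5,
                       seed=12345)


@pytest.fixture
def small_params() -> ModelParams:
    """Desk-scale population for exact stepping tests."""
    return ModelParams(n_cells=50, r0=0.5, delta=0.25, apoptosis_prob=0.6,
                       seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
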