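import numpy as np
import pytest

from damseg import ModelParams


@pytest.fixture
def default_params() -> ModelParams:
    """Reference parameter point: both modes' steady states exist
    (symmetric d* = 0.125, asymmetric d* = 1/9)."""
    return ModelParams(n=100, epsilon=0.1, p=0.1, delta=0.2, seed=1)


@pytest.fixture
def tiny_params() -> ModelParams:
    """Two-level damage lattice (0.5, 1.0): the smallest nontrivial chain."""
    return ModelParams(n=3, epsilon=0.5, p=0.3, delta=1.0, seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
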