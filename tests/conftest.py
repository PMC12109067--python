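import numpy as np
import pytest

from hcdm import ModelParams, build_mixed
from hcdm.training import precompute_features


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_mixed():
    """A small balanced mixed dataset shared across tests."""
    return build_mixed(160, seed=777)


@pytest.fixture(scope="session")
def small_mixed_features(small_mixed):
    return precompute_features(small_mixed)


@pytest.fixture
def tiny_params():
    return ModelParams.init_random(2, rng=5)
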