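import numpy as np
import pytest
from hypothesis import settings

from domrev.simulator import SimConfig

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A small, fast simulation configuration for unit tests."""
    return SimConfig(N=50, n_generations=20, seed=7)
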