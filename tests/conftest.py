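import numpy as np
import pytest

from pggsim import build_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return build_config()


@pytest.fixture
def small_config():
    """Baseline parameters at a desk-test scale."""
    return build_config(N0=50, T=50, I=3)
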