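import numpy as np
import pytest

from flickerdur.synthetic import ObserverParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_observer():
    return ObserverParams(rng_seed=42)


@pytest.fixture
def dilating_observer():
    """Observer with the default 33% dilation gain and moderate noise."""
    return ObserverParams(dilation_gain=0.33, duration_noise_sd=0.3, rng_seed=7)
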