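import numpy as np
import pytest
from hypothesis import settings

from ispc.preprocess import Signal

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_signal(rng):
    """Short gaussian white-noise signal, zero-meaned."""
    x = rng.standard_normal(4000)
    return Signal(x - x.mean(), fs=500.0, meta="unit-test noise")


@pytest.fixture
def sinusoid_signal():
    fs, n, f0 = 200.0, 4000, 20.0
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * f0 * t)
    return Signal(x - x.mean(), fs=fs, meta="20 Hz sinusoid")
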