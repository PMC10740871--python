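import numpy as np
import pytest

import rppglite.nn.layers as nn_layers
from rppglite.signal import HR_BAND, Signal1D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def float64_network():
    """Run the network in float64 so finite-difference checks are meaningful."""
    saved = nn_layers.DTYPE
    nn_layers.DTYPE = np.float64
    yield
    nn_layers.DTYPE = saved


@pytest.fixture
def band():
    return HR_BAND


def tone(freq_hz: float, fs: float = 30.0, n: int = 300, phase: float = 0.0) -> Signal1D:
    t = np.arange(n) / fs
    return Signal1D(np.sin(2 * np.pi * freq_hz * t + phase), fs)


@pytest.fixture
def make_tone():
    return tone
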