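import numpy as np
import pytest

from pulsefuse.signal_core import Signal1D


@pytest.fixture
def tone():
    """Factory for a pure sinusoid Signal1D."""

    def make(freq_hz: float, fs: float = 30.0, duration_s: float = 60.0,
             amplitude: float = 1.0, phase: float = 0.0) -> Signal1D:
        t = np.arange(int(round(duration_s * fs))) / fs
        return Signal1D(amplitude * np.sin(2 * np.pi * freq_hz * t + phase), fs)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
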