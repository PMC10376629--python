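import numpy as np
import pytest

from wavehrv import SampledSignal


@pytest.fixture
def sine():
    """Factory: a pure sine SampledSignal."""

    def make(freq=1.2, fs=32.0, duration=30.0, amp=1.0, phase=0.0):
        t = np.arange(0, duration, 1.0 / fs)
        return SampledSignal(amp * np.sin(2 * np.pi * freq * t + phase), fs)

    return make


def dominant_frequency(sig: SampledSignal) -> float:
    """Frequency of the largest FFT magnitude (DC excluded)."""
    x = sig.values - sig.values.mean()
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), 1.0 / sig.fs)
    return float(freqs[np.argmax(spec)])
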