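import numpy as np
import pytest

from hipposlice.signal_core import LfpRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_rec(rng):
    return LfpRecording(samples=rng.standard_normal(100_000), fs_hz=10_000.0)


def sinusoid_rec(freq_hz, fs_hz=10_000.0, duration_s=2.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs_hz)) / fs_hz
    return LfpRecording(samples=amplitude * np.sin(2 * np.pi * freq_hz * t + phase), fs_hz=fs_hz)


def fit_sinusoid_amplitude(samples, fs_hz, freq_hz):
    """Analytic amplitude of the freq_hz component via least squares."""
    t = np.arange(samples.size) / fs_hz
    design = np.column_stack([np.sin(2 * np.pi * freq_hz * t), np.cos(2 * np.pi * freq_hz * t)])
    coef, *_ = np.linalg.lstsq(design, samples, rcond=None)
    return float(np.hypot(*coef))
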