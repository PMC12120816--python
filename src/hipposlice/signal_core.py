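"""Shared filtering, spectral and autocorrelation primitives.

All filters are 4th-order Butterworth applied forward-backward
(:func:`scipy.signal.filtfilt`), giving a zero-phase response: in-band
event peaks are not shifted in time.  Spectra are averaged modified
periodograms (Hann window, 50% overlap) whose window length is chosen
to honour a requested frequency resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "LfpRecording",
    "Spectrum",
    "lowpass",
    "bandpass",
    "power_spectrum",
    "autocorrelation",
]

#: Default spectral resolution (Hz) of the averaged periodogram.
DEFAULT_RESOLUTION_HZ = 0.8192

FILTER_ORDER = 4


@dataclass(frozen=True)
class LfpRecording:
    """A uniformly sampled field-potential trace in millivolts."""

    samples: np.ndarray
    fs_hz: float
    t0_s: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 2:
            raise ValueError("recording needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz

    def with_samples(self, samples: np.ndarray) -> "LfpRecording":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class Spectrum:
    """Power spectrum on a uniform frequency grid.

    ``power_mv2`` holds per-bin power in mV^2 (power spectral density
    multiplied by the bin width), so a plain sum over bins integrates
    power and, by Parseval, approximates the mean squared amplitude of
    the analysed signal.
    """

    freqs_hz: np.ndarray
    power_mv2: np.ndarray
    resolution_hz: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs_hz, dtype=np.float64)
        power = np.asarray(self.power_mv2, dtype=np.float64)
        if freqs.shape != power.shape:
            raise ValueError("freqs_hz and power_mv2 must have the same shape")
        if np.any(power < 0):
            raise ValueError("power must be nonnegative")
        spacing = np.diff(freqs)
        if spacing.size and not np.allclose(spacing, self.resolution_hz, rtol=1e-6):
            raise ValueError("frequency grid must be uniform at resolution_hz")
        object.__setattr__(self, "freqs_hz", freqs)
        object.__setattr__(self, "power_mv2", power)

    def band_slice(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        """Boolean mask of bins whose centre lies in [lo_hz, hi_hz]."""
        if lo_hz < self.freqs_hz[0] - self.resolution_hz / 2 or hi_hz > self.freqs_hz[-1] + self.resolution_hz / 2:
            raise ValueError(f"band ({lo_hz}, {hi_hz}) Hz outside spectrum grid")
        return (self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz)

    def integrate(self, lo_hz: float, hi_hz: float) -> float:
        """Integrated power (mV^2) over a band, as a sum of bin powers."""
        return float(np.sum(self.power_mv2[self.band_slice(lo_hz, hi_hz)]))

    @property
    def total_power_mv2(self) -> float:
        return float(np.sum(self.power_mv2))


def _check_band(fs_hz: float, *edges: float) -> None:
    nyq = fs_hz / 2.0
    for e in edges:
        if not 0 < e < nyq:
            raise ValueError(f"filter edge {e} Hz outside (0, {nyq}) Hz")


def _filtfilt(rec: LfpRecording, sos: np.ndarray) -> LfpRecording:
    # reflect padding; padlen capped for short traces
    padlen = min(3 * (2 * FILTER_ORDER + 1), rec.n_samples - 1)
    out = sps.sosfiltfilt(sos, rec.samples, padtype="even", padlen=padlen)
    return rec.with_samples(out)


def lowpass(rec: LfpRecording, cutoff_hz: float) -> LfpRecording:
    """Zero-phase 4th-order Butterworth low-pass."""
    _check_band(rec.fs_hz, cutoff_hz)
    sos = sps.butter(FILTER_ORDER, cutoff_hz, btype="low", fs=rec.fs_hz, output="sos")
    return _filtfilt(rec, sos)


def bandpass(rec: LfpRecording, lo_hz: float, hi_hz: float) -> LfpRecording:
    """Zero-phase 4th-order Butterworth band-pass."""
    if lo_hz >= hi_hz:
        raise ValueError(f"inverted band: ({lo_hz}, {hi_hz})")
    _check_band(rec.fs_hz, lo_hz, hi_hz)
    sos = sps.butter(FILTER_ORDER, (lo_hz, hi_hz), btype="band", fs=rec.fs_hz, output="sos")
    return _filtfilt(rec, sos)


def power_spectrum(rec: LfpRecording, resolution_hz: float = DEFAULT_RESOLUTION_HZ) -> Spectrum:
    """Averaged modified periodogram (Hann, 50% overlap).

    The window length is ``round(fs_hz / resolution_hz)`` samples;
    segments that would cross the end of the trace are dropped.  The
    returned power is per-bin power in mV^2 so that summing bins
    integrates power.
    """
    nperseg = int(round(rec.fs_hz / resolution_hz))
    if rec.n_samples < nperseg:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than one analysis "
            f"window ({nperseg} samples)"
        )
    freqs, psd = sps.welch(
        rec.samples,
        fs=rec.fs_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )
    df = float(freqs[1] - freqs[0])
    return Spectrum(freqs_hz=freqs, power_mv2=psd * df, resolution_hz=df)


def autocorrelation(rec: LfpRecording, max_lag_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized autocorrelation over nonnegative lags.

    Returns ``(lags_s, coefficients)`` with the lag-0 coefficient
    exactly 1.  The mean is removed before correlating.  Callers that
    follow the low-frequency-rhythmicity convention should low-pass the
    trace (< 100 Hz) first.
    """
    if max_lag_s >= rec.duration_s:
        raise ValueError("max_lag_s must be shorter than the recording")
    x = rec.samples - rec.samples.mean()
    n = x.size
    max_lag = int(round(max_lag_s * rec.fs_hz))
    full = sps.fftconvolve(x, x[::-1], mode="full")
    r = full[n - 1 : n + max_lag]
    denom = r[0]
    if denom <= 0:  # constant trace
        coeffs = np.zeros_like(r)
        coeffs[0] = 1.0
    else:
        coeffs = r / denom
    lags = np.arange(max_lag + 1) / rec.fs_hz
    return lags, coeffs
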