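"""Carbachol-gamma metrics, slice exclusion, and autocorrelation rhythmicity.

Peak frequency/power and 20-60 Hz integrated power come from the
averaged periodogram; the peak search is restricted to the gamma band.
Recordings whose integrated power falls below 1e-5 mV^2 or whose peak
frequency lies below 20 Hz are flagged for exclusion.  Rhythmicity is
the second positive peak of the autocorrelation of the < 100 Hz
low-passed trace, with lag 0 counted as the first peak by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal_core import LfpRecording, Spectrum, autocorrelation, lowpass

__all__ = ["GammaMetrics", "gamma_metrics", "apply_exclusion", "autocorr_second_peak"]

GAMMA_BAND_HZ = (20.0, 60.0)
MIN_INTEGRATED_POWER_MV2 = 1e-5
MIN_PEAK_FREQUENCY_HZ = 20.0
AUTOCORR_LOWPASS_HZ = 100.0
AUTOCORR_MAX_LAG_S = 0.1
MIN_RHYTHMICITY_COEFFICIENT = 0.1


@dataclass(frozen=True)
class GammaMetrics:
    peak_frequency_hz: float
    peak_power_mv2: float
    integrated_power_mv2: float
    autocorr_second_peak: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "peak_frequency_hz": self.peak_frequency_hz,
            "peak_power_mv2": self.peak_power_mv2,
            "integrated_power_mv2": self.integrated_power_mv2,
            "autocorr_second_peak": self.autocorr_second_peak,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
        }


def gamma_metrics(spec: Spectrum, band: tuple = GAMMA_BAND_HZ) -> GammaMetrics:
    """Peak frequency, peak power, and integrated power within the band."""
    mask = spec.band_slice(*band)
    if not mask.any():
        raise ValueError("spectrum has no bins in the requested band")
    in_band_power = spec.power_mv2[mask]
    in_band_freqs = spec.freqs_hz[mask]
    imax = int(np.argmax(in_band_power))
    return GammaMetrics(
        peak_frequency_hz=float(in_band_freqs[imax]),
        peak_power_mv2=float(in_band_power[imax]),
        integrated_power_mv2=float(np.sum(in_band_power)),
    )


def apply_exclusion(metrics: GammaMetrics) -> GammaMetrics:
    """Flag slices below the power or peak-frequency floor; idempotent."""
    reasons = []
    if metrics.integrated_power_mv2 < MIN_INTEGRATED_POWER_MV2:
        reasons.append("integrated_power_below_1e-5_mv2")
    if metrics.peak_frequency_hz < MIN_PEAK_FREQUENCY_HZ:
        reasons.append("peak_frequency_below_20_hz")
    if not reasons:
        return metrics
    return replace(metrics, excluded=True, exclusion_reason="; ".join(reasons))


def autocorr_second_peak(
    rec: LfpRecording,
    max_lag_s: float = AUTOCORR_MAX_LAG_S,
    lowpass_hz: float = AUTOCORR_LOWPASS_HZ,
    lag0_counts: bool = True,
    min_coefficient: float | None = None,
) -> tuple[float | None, float | None]:
    """Value and lag of the second positive autocorrelation peak.

    The trace is low-passed (< 100 Hz) and autocorrelated; positive
    peaks are local maxima of the correlogram with positive coefficient.
    With ``lag0_counts`` (default) lag 0 is the first positive peak and
    the returned value sits one oscillation period out; otherwise the
    one-period peak counts as first and the two-period peak is returned.
    Peaks below ``min_coefficient`` (default 0.1) do not qualify: the
    low-pass filter itself leaves deterministic autocorrelation
    sidelobes of ~0.05 on aperiodic input, so an unrhythmic trace must
    not report a peak.  Returns ``(value, lag_s)``, or ``(None, None)``
    when no qualifying peak exists.
    """
    filtered = lowpass(rec, lowpass_hz)
    lags, coeffs = autocorrelation(filtered, max_lag_s)
    if min_coefficient is None:
        min_coefficient = MIN_RHYTHMICITY_COEFFICIENT
    interior = np.flatnonzero(
        (coeffs[1:-1] > coeffs[:-2]) & (coeffs[1:-1] > coeffs[2:])
    ) + 1
    qualifying = [i for i in interior if coeffs[i] > max(0.0, min_coefficient)]
    want = 1 if lag0_counts else 2
    if len(qualifying) < want:
        return None, None
    i = qualifying[want - 1]
    return float(coeffs[i]), float(lags[i])
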