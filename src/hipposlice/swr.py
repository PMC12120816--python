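"""Sharp-wave-ripple detection and quantification.

Detection: the trace is low-pass filtered at 45 Hz, mean-subtracted and
polarity-resolved; local maxima exceeding 2.5 SD of the filtered trace
are sharp-wave candidates, thinned to a minimum 80 ms separation (the
larger peak wins a conflict).  Quantification: SW area is the
trapezoidal integral of the 125 ms event window between the mean
crossings flanking the peak; ripple statistics come from the 120-300 Hz
band-passed raw data in a 25 ms window around the peak, thresholded at
3 SD of the whole band-passed trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import LfpRecording, bandpass, lowpass

__all__ = [
    "SwrParams",
    "SwrEvent",
    "detect_sharp_waves",
    "sw_area",
    "analyze_ripples",
    "quantify_events",
    "swr_summary",
]


@dataclass(frozen=True)
class SwrParams:
    sw_lowpass_hz: float = 45.0
    sw_threshold_sd: float = 2.5
    min_interval_ms: float = 80.0
    sw_window_ms: float = 125.0
    ripple_band_hz: tuple = (120.0, 300.0)
    ripple_threshold_sd: float = 3.0
    ripple_window_ms: float = 25.0
    polarity: str = "absolute"  # {"positive", "negative", "absolute"}

    def __post_init__(self) -> None:
        if self.sw_threshold_sd <= 0 or self.ripple_threshold_sd <= 0:
            raise ValueError("thresholds must be positive")
        if min(self.min_interval_ms, self.sw_window_ms, self.ripple_window_ms) <= 0:
            raise ValueError("windows must be positive")
        lo, hi = self.ripple_band_hz
        if not 0 < lo < hi:
            raise ValueError("invalid ripple band")
        if self.polarity not in ("positive", "negative", "absolute"):
            raise ValueError("polarity must be positive, negative or absolute")


@dataclass
class SwrEvent:
    """One detected sharp wave and its quantification."""

    peak_time_s: float
    peak_index: int
    peak_amplitude_mv: float
    sw_window_mv: np.ndarray | None = None  # 125 ms polarity-resolved low-pass stretch
    window_fs_hz: float | None = None
    sw_area_mv_ms: float | None = None
    ripple_count: int = 0
    ripple_amplitude_mv: float | None = None
    ripple_frequency_hz: float | None = None
    flags: list = field(default_factory=list)


def _resolve_polarity(x: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "positive":
        return x
    if polarity == "negative":
        return -x
    return np.abs(x)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima."""
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1


def detect_sharp_waves(rec: LfpRecording, params: SwrParams = SwrParams()) -> list[SwrEvent]:
    """Sharp-wave peak positions (quantification fields left empty).

    A zero-variance (constant) trace yields zero events; a trace shorter
    than one analysis window is an error.
    """
    win = int(round(params.sw_window_ms / 1000.0 * rec.fs_hz))
    if rec.n_samples < win:
        raise ValueError("recording shorter than one sharp-wave window")
    filtered = lowpass(rec, params.sw_lowpass_hz).samples
    filtered = filtered - filtered.mean()
    sd = filtered.std()
    if sd == 0:
        return []
    x = _resolve_polarity(filtered, params.polarity)
    threshold = params.sw_threshold_sd * sd

    candidates = _local_maxima(x)
    candidates = candidates[x[candidates] > threshold]

    # drop events whose 125 ms window would cross the trace boundary
    half = win // 2
    candidates = candidates[(candidates >= half) & (candidates + half < rec.n_samples)]

    # refractory thinning: larger amplitude wins a < min_interval conflict
    min_gap = int(round(params.min_interval_ms / 1000.0 * rec.fs_hz))
    order = candidates[np.argsort(x[candidates])[::-1]]
    accepted: list[int] = []
    for idx in order:
        if all(abs(idx - a) >= min_gap for a in accepted):
            accepted.append(int(idx))
    accepted.sort()

    events = []
    for idx in accepted:
        events.append(
            SwrEvent(
                peak_time_s=rec.t0_s + idx / rec.fs_hz,
                peak_index=idx,
                peak_amplitude_mv=float(x[idx]),
            )
        )
    return events


def extract_window(signal: np.ndarray, center: int, win_samples: int) -> np.ndarray:
    half = win_samples // 2
    return signal[center - half : center - half + win_samples]


def sw_area(
    window_mv: np.ndarray,
    fs_hz: float,
    window_mean: float | None = None,
    peak_index: int | None = None,
) -> tuple[float, bool]:
    """Trapezoidal SW area (mV·ms) between the mean crossings around the peak.

    Integrates ``window - mean`` from the last crossing of the window
    mean before the peak to the first crossing after it; crossing points
    are linearly interpolated.  Returns ``(area, edge_flag)`` where the
    flag marks integration truncated at a window edge because no
    crossing exists on that side.
    """
    w = np.asarray(window_mv, dtype=np.float64)
    if w.size < 2:
        raise ValueError("window too short")
    mean = float(np.mean(w)) if window_mean is None else float(window_mean)
    y = w - mean
    peak = int(np.argmax(y)) if peak_index is None else int(peak_index)
    if y[peak] <= 0:
        return 0.0, False

    below = y <= 0
    flagged = False
    pre = np.flatnonzero(below[: peak + 1])
    if pre.size:
        i0 = int(pre[-1])
    else:
        i0, flagged = 0, True
    post = np.flatnonzero(below[peak:])
    if post.size:
        i1 = peak + int(post[0])
    else:
        i1, flagged = y.size - 1, True

    seg = y[i0 : i1 + 1].copy()
    # interpolate the sub-sample crossing at each end
    dt = 1.0 / fs_hz
    t = np.arange(seg.size) * dt
    if seg[0] < 0:
        frac = seg[0] / (seg[0] - seg[1])  # position of zero between samples 0 and 1
        t[0] = frac * dt
        seg[0] = 0.0
    if seg[-1] < 0:
        frac = seg[-2] / (seg[-2] - seg[-1])
        t[-1] = t[-2] + frac * dt
        seg[-1] = 0.0
    area_mv_s = float(np.trapezoid(np.clip(seg, 0.0, None), t))
    return area_mv_s * 1000.0, flagged


def analyze_ripples(
    banded: np.ndarray,
    band_sd: float,
    peak_index: int,
    fs_hz: float,
    params: SwrParams = SwrParams(),
) -> tuple[int, float | None, float | None, list]:
    """Ripple count, amplitude and frequency in the 25 ms event window.

    ``banded`` is the whole band-pass-filtered recording and ``band_sd``
    its global SD (the threshold is global, not per-window).  Per-ripple
    amplitude is the mean of the rising (peak minus preceding trough)
    and falling (peak minus following trough) components; the event
    amplitude averages over ripples.  Frequency is the mean reciprocal
    inter-peak interval and requires at least two ripples.
    """
    win = int(round(params.ripple_window_ms / 1000.0 * fs_hz))
    half = win // 2
    lo = max(0, peak_index - half)
    hi = min(banded.size, peak_index - half + win)
    seg = banded[lo:hi]
    flags: list = []
    if seg.size < 3:
        return 0, None, None, ["ripple_window_truncated"]

    threshold = params.ripple_threshold_sd * band_sd
    peaks = _local_maxima(seg)
    peaks = peaks[seg[peaks] > threshold]
    if peaks.size == 0:
        return 0, None, None, flags

    minima = _local_maxima(-seg)
    amplitudes = []
    for p in peaks:
        before = minima[minima < p]
        after = minima[minima > p]
        rising_ref = seg[before[-1]] if before.size else seg[0]
        falling_ref = seg[after[0]] if after.size else seg[-1]
        if not before.size or not after.size:
            flags.append("ripple_edge_truncated")
        amplitudes.append(((seg[p] - rising_ref) + (seg[p] - falling_ref)) / 2.0)
    amplitude = float(np.mean(amplitudes))

    frequency = None
    if peaks.size >= 2:
        # parabolic sub-sample refinement removes the one-sample
        # quantization bias of the reciprocal-interval estimator
        refined = []
        for p in peaks:
            if 0 < p < seg.size - 1:
                denom = seg[p - 1] - 2 * seg[p] + seg[p + 1]
                shift = 0.5 * (seg[p - 1] - seg[p + 1]) / denom if denom != 0 else 0.0
                refined.append(p + float(np.clip(shift, -0.5, 0.5)))
            else:
                refined.append(float(p))
        intervals_s = np.diff(refined) / fs_hz
        frequency = float(np.mean(1.0 / intervals_s))
    return int(peaks.size), amplitude, frequency, flags


def quantify_events(
    rec: LfpRecording, events: list[SwrEvent], params: SwrParams = SwrParams()
) -> list[SwrEvent]:
    """Fill SW-area and ripple fields of detected events in place."""
    if not events:
        return events
    filtered = lowpass(rec, params.sw_lowpass_hz).samples
    filtered = _resolve_polarity(filtered - filtered.mean(), params.polarity)
    banded = bandpass(rec, *params.ripple_band_hz).samples
    band_sd = float(banded.std())
    win = int(round(params.sw_window_ms / 1000.0 * rec.fs_hz))
    for ev in events:
        window = extract_window(filtered, ev.peak_index, win)
        ev.sw_window_mv = window
        ev.window_fs_hz = rec.fs_hz
        area, edge = sw_area(window, rec.fs_hz, peak_index=window.size // 2)
        ev.sw_area_mv_ms = area
        if edge:
            ev.flags.append("area_edge_truncated")
        count, amp, freq, rflags = analyze_ripples(
            banded, band_sd, ev.peak_index, rec.fs_hz, params
        )
        ev.ripple_count = count
        ev.ripple_amplitude_mv = amp
        ev.ripple_frequency_hz = freq
        ev.flags.extend(rflags)
    return events


def detect_and_quantify(
    rec: LfpRecording, params: SwrParams = SwrParams()
) -> list[SwrEvent]:
    return quantify_events(rec, detect_sharp_waves(rec, params), params)


def swr_summary(events: list[SwrEvent], duration_s: float) -> dict:
    """Per-recording aggregation; means skip absent fields."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    areas = [e.sw_area_mv_ms for e in events if e.sw_area_mv_ms is not None]
    amps = [e.ripple_amplitude_mv for e in events if e.ripple_amplitude_mv is not None]
    freqs = [e.ripple_frequency_hz for e in events if e.ripple_frequency_hz is not None]
    return {
        "n_events": len(events),
        "incidence_per_s": len(events) / duration_s,
        "mean_sw_area_mv_ms": float(np.mean(areas)) if areas else None,
        "mean_ripple_amplitude_mv": float(np.mean(amps)) if amps else None,
        "mean_ripple_frequency_hz": float(np.mean(freqs)) if freqs else None,
    }
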