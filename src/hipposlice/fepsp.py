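"""Evoked fEPSP quantification: slope, I-O curve, paired-pulse, LTP.

The fEPSP slope is a straight-line fit over the 20-80% span of the
initial rising phase of the deflection, measured after a short
post-stimulus blanking window and reported as a positive magnitude.
Paired-pulse second responses are corrected by mono-exponentially
extrapolating the decay tail of the first response before fitting.
LTP series are normalized so the pre-HFS baseline averages 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import PPR_ISIS_MS, FepspSweep

__all__ = [
    "SlopeConfig",
    "LtpSeries",
    "fepsp_slope",
    "io_curve",
    "half_max_intensity",
    "paired_pulse_ratio",
    "ltp_normalize",
    "ltp_summary",
]


@dataclass(frozen=True)
class SlopeConfig:
    blank_ms: float = 1.0  # post-stimulus artifact blanking
    fit_span: tuple = (0.2, 0.8)  # fraction of peak bounding the fit window
    response_window_ms: float = 50.0  # search window after blanking
    min_peak_mv: float = 0.01  # below this, "no detectable response"
    smooth_ms: float = 0.9  # Savitzky-Golay pre-smoothing window (0 disables)


def _segment_slope(
    trace: np.ndarray, fs_hz: float, start: int, stop: int, cfg: SlopeConfig
) -> tuple[float, bool]:
    """Slope (mV/ms, positive magnitude) of the response in trace[start:stop]."""
    seg = trace[start:stop]
    if seg.size < 5:
        return 0.0, True
    if cfg.smooth_ms > 0:
        win = int(round(cfg.smooth_ms / 1000.0 * fs_hz)) | 1  # odd
        if 5 <= win < seg.size:
            # quadratic Savitzky-Golay: exact on linear ramps, tames
            # sample noise before the peak search and level crossings
            from scipy.signal import savgol_filter

            seg = savgol_filter(seg, win, 2)
    baseline = seg[0]
    y = seg - baseline
    # polarity: sign of the dominant deflection
    sign = 1.0 if np.max(y) >= -np.min(y) else -1.0
    y = sign * y
    ipk = int(np.argmax(y))
    peak = y[ipk]
    if peak < cfg.min_peak_mv:
        return 0.0, True
    lo_level, hi_level = cfg.fit_span[0] * peak, cfg.fit_span[1] * peak
    # walk back from the peak to the last crossings of each level
    rising = y[: ipk + 1]
    below_lo = np.flatnonzero(rising <= lo_level)
    below_hi = np.flatnonzero(rising <= hi_level)
    i_lo = int(below_lo[-1]) if below_lo.size else 0
    i_hi = int(below_hi[-1]) + 1 if below_hi.size else ipk
    i_hi = min(i_hi, ipk)
    if i_hi - i_lo < 2:
        i_lo, i_hi = max(0, ipk - 3), ipk
    t_ms = np.arange(i_lo, i_hi + 1) / fs_hz * 1000.0
    coeffs = np.polyfit(t_ms, y[i_lo : i_hi + 1], 1)
    return float(abs(coeffs[0])), False


def _response_bounds(
    sweep: FepspSweep, stim_s: float, cfg: SlopeConfig, stop_s: float | None = None
) -> tuple[int, int]:
    start = int(round((stim_s + cfg.blank_ms / 1000.0) * sweep.fs_hz))
    stop_default = stim_s + cfg.blank_ms / 1000.0 + cfg.response_window_ms / 1000.0
    stop = int(round(min(stop_s if stop_s is not None else stop_default, sweep.duration_s) * sweep.fs_hz))
    return start, min(stop, sweep.trace_mv.size)


def fepsp_slope(sweep: FepspSweep, cfg: SlopeConfig = SlopeConfig()) -> tuple[float, bool]:
    """Slope of the first (or only) evoked response.

    Returns ``(slope_mv_per_ms, flagged)``; a flagged zero means no
    detectable response after the blanking window.
    """
    stim = sweep.stim_times_s[0]
    stop_s = sweep.stim_times_s[1] if len(sweep.stim_times_s) == 2 else None
    start, stop = _response_bounds(sweep, stim, cfg, stop_s)
    return _segment_slope(sweep.trace_mv, sweep.fs_hz, start, stop, cfg)


def io_curve(sweeps: Sequence[FepspSweep], cfg: SlopeConfig = SlopeConfig()) -> pd.DataFrame:
    """Mean slope per stimulation intensity, ascending in intensity."""
    rows = []
    for sw in sweeps:
        slope, flagged = fepsp_slope(sw, cfg)
        rows.append({"intensity_ua": sw.stim_intensity_ua, "slope_mv_per_ms": slope,
                     "flagged": flagged})
    df = pd.DataFrame(rows)
    out = (
        df.groupby("intensity_ua", sort=True)["slope_mv_per_ms"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_slope_mv_per_ms", "sem": "sem_slope_mv_per_ms",
                         "count": "n_sweeps"})
    )
    return out


def half_max_intensity(curve: pd.DataFrame) -> tuple[float, bool]:
    """Tested intensity whose mean slope is closest to half the maximum.

    Ties go to the lower intensity.  Returns ``(intensity_ua, degenerate)``
    where the flag marks an all-equal (uninformative) curve.
    """
    if curve.empty:
        raise ValueError("empty I-O curve")
    slopes = curve["mean_slope_mv_per_ms"].to_numpy()
    intensities = curve["intensity_ua"].to_numpy()
    order = np.argsort(intensities, kind="stable")
    slopes, intensities = slopes[order], intensities[order]
    target = 0.5 * float(np.max(slopes))
    dist = np.abs(slopes - target)
    best = int(np.argmin(dist))  # argmin takes the first (lowest intensity) tie
    degenerate = bool(np.allclose(slopes, slopes[0]))
    return float(intensities[best]), degenerate


def _fit_exp_tail(
    y: np.ndarray, fs_hz: float
) -> tuple[float, float] | None:
    """Fit y ~ a*exp(-t/tau) on a positive-valued segment; None if it fails."""
    if y.size < 5 or np.any(y <= 0):
        return None
    t = np.arange(y.size) / fs_hz
    b, log_a = np.polyfit(t, np.log(y), 1)
    if b >= 0:
        return None
    return float(np.exp(log_a)), float(-1.0 / b)


def paired_pulse_ratio(
    sweep: FepspSweep, cfg: SlopeConfig = SlopeConfig()
) -> tuple[float | None, bool]:
    """slope2 / slope1 for a two-stimulus sweep.

    The decaying tail of the first response is extrapolated
    mono-exponentially and subtracted before measuring the second
    slope; the correction is skipped when the residual tail at the
    second stimulus is negligible.  Returns ``(ratio, flagged)``;
    ``None`` with a flag when the first slope is undefined or zero.
    """
    if len(sweep.stim_times_s) != 2:
        raise ValueError("paired-pulse analysis needs exactly two stimuli")
    isi_ms = (sweep.stim_times_s[1] - sweep.stim_times_s[0]) * 1000.0
    if not any(np.isclose(isi_ms, a, atol=0.5) for a in PPR_ISIS_MS):
        raise ValueError(f"ISI {isi_ms:.1f} ms outside protocol set {PPR_ISIS_MS}")
    slope1, flag1 = fepsp_slope(sweep, cfg)
    if flag1 or slope1 == 0.0:
        return None, True

    stim1, stim2 = sweep.stim_times_s
    fs = sweep.fs_hz
    trace = sweep.trace_mv
    i_stim2 = int(round(stim2 * fs))
    start1, stop1 = _response_bounds(sweep, stim1, cfg, stim2)
    seg1 = trace[start1:stop1]
    base = seg1[0]
    sign = 1.0 if np.max(seg1 - base) >= -np.min(seg1 - base) else -1.0
    y1 = sign * (seg1 - base)
    ipk1 = int(np.argmax(y1))
    peak1 = y1[ipk1]

    corrected = trace.copy()
    tail_at_stim2 = sign * (trace[i_stim2 - 1] - base) if i_stim2 > 0 else 0.0
    if tail_at_stim2 > 0.02 * peak1:
        # fit the decay between first peak and second stimulus, extrapolate past it
        tail_start = start1 + ipk1 + max(2, int(0.0005 * fs))
        tail = sign * (trace[tail_start:i_stim2] - base)
        fit = _fit_exp_tail(tail, fs)
        if fit is not None:
            a, tau = fit
            t_ext = np.arange(corrected.size - tail_start) / fs
            corrected[tail_start:] -= sign * a * np.exp(-t_ext / tau)

    start2, stop2 = _response_bounds(sweep, stim2, cfg)
    slope2, flag2 = _segment_slope(corrected, fs, start2, stop2, cfg)
    if flag2:
        return None, True
    return slope2 / slope1, False


@dataclass
class LtpSeries:
    """Time-stamped normalized fEPSP slopes around an HFS marker at t=0."""

    times_min: np.ndarray
    normalized_slope_pct: np.ndarray
    baseline_window_min: tuple
    hfs_time_s: float
    baseline_mean_slope: float
    flags: list = field(default_factory=list)


def ltp_normalize(
    sweeps: Sequence[FepspSweep],
    hfs_time_s: float = 0.0,
    baseline_min: float = 10.0,
    cfg: SlopeConfig = SlopeConfig(),
) -> LtpSeries:
    """Normalize sweep slopes to the mean of the pre-HFS baseline (=100%)."""
    times_min = np.array([(sw.timestamp_s - hfs_time_s) / 60.0 for sw in sweeps])
    slopes = np.array([fepsp_slope(sw, cfg)[0] for sw in sweeps])
    order = np.argsort(times_min, kind="stable")
    times_min, slopes = times_min[order], slopes[order]
    in_baseline = (times_min >= -baseline_min) & (times_min < 0)
    if not in_baseline.any():
        raise ValueError("no sweeps in the baseline window")
    base = float(slopes[in_baseline].mean())
    if base == 0:
        raise ValueError("baseline slope is zero; cannot normalize")
    return LtpSeries(
        times_min=times_min,
        normalized_slope_pct=slopes / base * 100.0,
        baseline_window_min=(-baseline_min, 0.0),
        hfs_time_s=hfs_time_s,
        baseline_mean_slope=base,
    )


def ltp_summary(series: LtpSeries, last_window_min: float = 10.0) -> dict:
    """Mean +/- SEM of normalized slope over the final window of the series."""
    t_end = float(series.times_min.max())
    mask = (series.times_min >= t_end - last_window_min) & (series.times_min > 0)
    if not mask.any():
        raise ValueError("no post-HFS sweeps in the final window")
    vals = series.normalized_slope_pct[mask]
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return {"mean_pct": float(vals.mean()), "sem_pct": sem, "n_sweeps": int(vals.size),
            "window_min": (t_end - last_window_min, t_end)}
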