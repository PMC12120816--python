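"""Synthetic generators for every input the pipeline consumes.

Each generator implants structure with a known ground truth so that the
detection and quantification stages can be verified end to end without
any external data.  A single global seed is expanded into independent
per-component substreams, so adding one generator does not perturb the
draws of another.

The waveform shapes (sharp-wave template, EPSP kernel, Gaussian puncta)
are deliberately simple: only the detection/quantification logic is
under test, not the biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signal_core import LfpRecording

__all__ = [
    "LfpSimConfig",
    "GroundTruth",
    "simulate_lfp",
    "simulate_gamma",
    "simulate_fepsp_series",
    "simulate_io_sweeps",
    "simulate_spines",
    "simulate_segment",
    "simulate_puncta_image",
    "epsp_kernel",
    "SPINE_CLASSES",
]

# Substream indices for the global-seed expansion.
_STREAMS = {
    "lfp_noise": 0,
    "lfp_events": 1,
    "gamma": 2,
    "fepsp": 3,
    "spines": 4,
    "puncta": 5,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[component]])


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


@dataclass(frozen=True)
class LfpSimConfig:
    """Parameters of the sharp-wave-ripple LFP simulation."""

    duration_s: float = 120.0
    fs_hz: float = 10_000.0
    noise_model: str = "pink"  # {"pink", "white"}
    noise_amplitude_mv: float = 0.05
    sw_rate_hz: float = 0.2
    sw_amplitude_mv: float = 0.3
    sw_halfwidth_ms: float = 40.0
    ripple_freq_hz: float = 200.0
    ripple_amplitude_mv: float = 0.1
    ripple_halfwidth_ms: float = 8.0
    sw_polarity: int = 1  # +1 or -1 deflection
    min_interval_s: float = 0.08
    n_events: int | None = None  # exact count overrides the Poisson draw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.fs_hz < 2 * self.ripple_freq_hz:
            raise ValueError(
                f"fs_hz={self.fs_hz} below Nyquist for ripple_freq_hz={self.ripple_freq_hz}"
            )
        if self.sw_rate_hz < 0:
            raise ValueError("sw_rate_hz must be nonnegative")
        for name in ("noise_amplitude_mv", "sw_amplitude_mv", "ripple_amplitude_mv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.noise_model not in ("pink", "white"):
            raise ValueError("noise_model must be 'pink' or 'white'")
        if self.sw_polarity not in (1, -1):
            raise ValueError("sw_polarity must be +1 or -1")


@dataclass
class GroundTruth:
    """Implanted truth of a simulation, for detector verification."""

    event_times_s: list = field(default_factory=list)
    event_amplitudes_mv: list = field(default_factory=list)
    ripple_freq_hz: float | None = None
    osc_freq_hz: float | None = None
    osc_amplitude_mv: float | None = None
    max_slope_mv_per_ms: float | None = None
    potentiation_factor: float | None = None
    ppr_factors: dict = field(default_factory=dict)
    coloc_pairs: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = list(self.event_times_s)
        if times != sorted(times):
            raise ValueError("event times must be sorted")
        if len(set(times)) != len(times):
            raise ValueError("event times must be strictly increasing")


def _sw_template(t_s: np.ndarray, halfwidth_ms: float) -> np.ndarray:
    """Smooth biphasic deflection (difference of Gaussians), peak 1."""
    sigma = halfwidth_ms / 1000.0 / 2.355  # FWHM -> sigma
    main = np.exp(-0.5 * (t_s / sigma) ** 2)
    rebound = 0.25 * np.exp(-0.5 * (t_s / (2.5 * sigma)) ** 2)
    tpl = main - rebound
    return tpl / tpl.max()


def simulate_lfp(config: LfpSimConfig) -> tuple[LfpRecording, GroundTruth]:
    """Background noise plus implanted sharp-wave-ripple events.

    Events are drawn from a Poisson-like process whose inter-event
    intervals are re-drawn until they respect ``min_interval_s`` (plus
    the template support), so implanted truth never violates the
    detector's refractory contract.
    """
    n = int(round(config.duration_s * config.fs_hz))
    noise_rng = _rng(config.seed, "lfp_noise")
    event_rng = _rng(config.seed, "lfp_events")

    if config.noise_model == "pink":
        noise = pink_noise(n, noise_rng)
    else:
        noise = noise_rng.standard_normal(n)
    trace = noise * config.noise_amplitude_mv

    # event placement: margin keeps the 125 ms analysis window in-bounds
    margin_s = 0.1
    spacing_s = max(config.min_interval_s, 2.5 * config.sw_halfwidth_ms / 1000.0)
    times: list[float] = []
    if config.n_events is not None:
        # exact count: rejection-sample uniform times respecting the spacing
        attempts = 0
        while len(times) < config.n_events:
            attempts += 1
            if attempts > 100_000:
                raise RuntimeError("cannot place events at the requested spacing")
            t = float(event_rng.uniform(margin_s, config.duration_s - margin_s))
            if all(abs(t - u) >= spacing_s for u in times):
                times.append(t)
        times.sort()
    elif config.sw_rate_hz > 0:
        t = margin_s
        while True:
            isi = event_rng.exponential(1.0 / config.sw_rate_hz)
            while isi < spacing_s:
                isi = event_rng.exponential(1.0 / config.sw_rate_hz)
            t += isi
            if t > config.duration_s - margin_s:
                break
            times.append(t)

    half_support = 3 * config.sw_halfwidth_ms / 1000.0
    ripple_half_s = 0.0125  # ripple burst confined to +/- 12.5 ms
    amplitudes = []
    for t_ev in times:
        i0 = max(0, int(round((t_ev - half_support) * config.fs_hz)))
        i1 = min(n, int(round((t_ev + half_support) * config.fs_hz)) + 1)
        t_rel = np.arange(i0, i1) / config.fs_hz - t_ev
        amp = config.sw_amplitude_mv * float(event_rng.uniform(0.85, 1.15))
        amplitudes.append(amp)
        trace[i0:i1] += config.sw_polarity * amp * _sw_template(t_rel, config.sw_halfwidth_ms)
        if config.ripple_amplitude_mv > 0:
            # flat envelope: a tapered (Gaussian/Tukey) envelope shifts
            # the burst's inter-peak intervals and biases the recovered
            # ripple frequency
            env = (np.abs(t_rel) <= ripple_half_s).astype(np.float64)
            phase = event_rng.uniform(0, 2 * np.pi)
            trace[i0:i1] += (
                config.ripple_amplitude_mv
                * env
                * np.sin(2 * np.pi * config.ripple_freq_hz * t_rel + phase)
            )

    rec = LfpRecording(samples=trace, fs_hz=config.fs_hz, label="sim_swr")
    truth = GroundTruth(
        event_times_s=times,
        event_amplitudes_mv=amplitudes,
        ripple_freq_hz=config.ripple_freq_hz if config.ripple_amplitude_mv > 0 else None,
    )
    return rec, truth


def standard_benchmark_config(seed: int = 1) -> LfpSimConfig:
    """Canonical SWR detection benchmark: 120 s at 10 kHz, exactly 20
    implanted events at 6x the noise SD, white background.

    White noise keeps the sub-45-Hz background far below the detection
    threshold, so detector errors — not background statistics — dominate
    the recall/precision figures.
    """
    return LfpSimConfig(
        duration_s=120.0,
        fs_hz=10_000.0,
        noise_model="white",
        noise_amplitude_mv=0.05,
        sw_amplitude_mv=0.3,  # 6x noise SD
        sw_rate_hz=0.2,
        n_events=20,
        ripple_freq_hz=200.0,
        ripple_amplitude_mv=0.1,
        seed=seed,
    )


def simulate_gamma(
    duration_s: float,
    fs_hz: float,
    osc_freq_hz: float,
    osc_amplitude_mv: float,
    noise_amplitude_mv: float,
    seed: int = 0,
    mod_depth: float = 0.2,
    noise_model: str = "pink",
) -> tuple[LfpRecording, GroundTruth]:
    """Stationary oscillation with slow random amplitude modulation plus noise."""
    if fs_hz < 2 * osc_freq_hz:
        raise ValueError("fs_hz below Nyquist for osc_freq_hz")
    if duration_s <= 0 or fs_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    rng = _rng(seed, "gamma")
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    if noise_amplitude_mv > 0:
        base = pink_noise(n, rng) if noise_model == "pink" else rng.standard_normal(n)
        trace = noise_amplitude_mv * base
    else:
        trace = np.zeros(n)
    if osc_amplitude_mv > 0:
        # slow (~1 Hz) envelope wobble
        slow = pink_noise(n, rng)
        k = max(1, int(fs_hz))  # ~1 s boxcar
        kernel = np.ones(k) / k
        slow = np.convolve(slow, kernel, mode="same")
        sd = slow.std()
        if sd > 0:
            slow = slow / sd
        envelope = 1.0 + mod_depth * slow
        envelope = np.clip(envelope, 0.1, None)
        phase = rng.uniform(0, 2 * np.pi)
        trace = trace + osc_amplitude_mv * envelope * np.sin(2 * np.pi * osc_freq_hz * t + phase)
    rec = LfpRecording(samples=trace, fs_hz=fs_hz, label="sim_gamma")
    truth = GroundTruth(osc_freq_hz=osc_freq_hz if osc_amplitude_mv > 0 else None,
                        osc_amplitude_mv=osc_amplitude_mv)
    return rec, truth


# ---------------------------------------------------------------------------
# fEPSP sweeps

PPR_ISIS_MS = (10.0, 20.0, 50.0, 100.0, 200.0)


def epsp_kernel(t_s: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Dual-exponential EPSP kernel, normalized to unit peak, zero for t<0."""
    if tau_rise_s >= tau_decay_s:
        raise ValueError("tau_rise must be shorter than tau_decay")
    y = np.where(t_s >= 0, np.exp(-t_s / tau_decay_s) - np.exp(-t_s / tau_rise_s), 0.0)
    t_peak = (
        tau_rise_s
        * tau_decay_s
        / (tau_decay_s - tau_rise_s)
        * np.log(tau_decay_s / tau_rise_s)
    )
    peak = np.exp(-t_peak / tau_decay_s) - np.exp(-t_peak / tau_rise_s)
    return y / peak


def _kernel_max_slope(tau_rise_s: float, tau_decay_s: float, fs_hz: float) -> float:
    """Max finite-difference slope (per ms) of the unit-peak kernel."""
    t = np.arange(0, 10 * tau_decay_s, 1 / fs_hz)
    y = epsp_kernel(t, tau_rise_s, tau_decay_s)
    return float(np.max(np.diff(y)) * fs_hz / 1000.0)


@dataclass(frozen=True)
class FepspSweep:
    """One evoked field response: trace plus stimulus metadata."""

    trace_mv: np.ndarray
    fs_hz: float
    stim_times_s: tuple
    stim_intensity_ua: float = 0.0
    timestamp_s: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        trace = np.asarray(self.trace_mv, dtype=np.float64)
        object.__setattr__(self, "trace_mv", trace)
        stims = tuple(float(t) for t in self.stim_times_s)
        if not 1 <= len(stims) <= 2:
            raise ValueError("a sweep carries one or two stimuli")
        dur = trace.size / self.fs_hz
        if any(not 0 <= t < dur for t in stims):
            raise ValueError("stimulus times must lie within the trace")
        object.__setattr__(self, "stim_times_s", stims)

    @property
    def duration_s(self) -> float:
        return self.trace_mv.size / self.fs_hz


DEFAULT_SWEEP_PARAMS = {
    "fs_hz": 10_000.0,
    "pre_stim_s": 0.01,
    "sweep_duration_s": 0.30,
    "amplitude_mv": 1.0,
    "tau_rise_s": 0.001,
    "tau_decay_s": 0.008,
    "artifact_mv": 4.0,
    "artifact_width_s": 0.0004,
    "response_delay_s": 0.002,
    "polarity": -1,  # stratum radiatum fEPSPs deflect negative
}


def _render_sweep(
    stim_times_s: Sequence[float],
    amplitudes_mv: Sequence[float],
    params: dict,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    fs = params["fs_hz"]
    n = int(round(params["sweep_duration_s"] * fs))
    t = np.arange(n) / fs
    trace = np.zeros(n)
    for stim, amp in zip(stim_times_s, amplitudes_mv):
        onset = stim + params["response_delay_s"]
        trace += (
            params["polarity"]
            * amp
            * epsp_kernel(t - onset, params["tau_rise_s"], params["tau_decay_s"])
        )
        art = (t >= stim) & (t < stim + params["artifact_width_s"])
        trace[art] += params["artifact_mv"]
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, n)
    return trace


def simulate_fepsp_series(
    n_baseline: int,
    n_post: int,
    sweep_params: dict | None = None,
    potentiation_factor: float = 1.5,
    ppr_factors_per_isi: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sweep_interval_s: float = 30.0,
) -> tuple[list[FepspSweep], GroundTruth]:
    """Baseline and post-HFS sweeps, plus optional paired-pulse sweeps.

    Baseline sweeps share one true maximal slope; post-HFS sweeps scale
    it by ``potentiation_factor``.  HFS sits at timestamp 0; baseline
    sweeps carry negative timestamps.  Paired-pulse sweeps (one per ISI
    in ``ppr_factors_per_isi``) scale the second response's amplitude by
    that ISI's factor.
    """
    if potentiation_factor <= 0:
        raise ValueError("potentiation_factor must be positive")
    params = dict(DEFAULT_SWEEP_PARAMS)
    if sweep_params:
        params.update(sweep_params)
    ppr_factors = dict(ppr_factors_per_isi or {})
    for isi_ms in ppr_factors:
        if float(isi_ms) not in PPR_ISIS_MS:
            raise ValueError(f"ISI {isi_ms} ms not in protocol set {PPR_ISIS_MS}")
    rng = _rng(seed, "fepsp")
    amp = params["amplitude_mv"]
    stim = params["pre_stim_s"]
    sweeps: list[FepspSweep] = []
    for i in range(n_baseline):
        ts = -(n_baseline - i) * sweep_interval_s
        trace = _render_sweep([stim], [amp], params, noise_sd, rng)
        sweeps.append(FepspSweep(trace, params["fs_hz"], (stim,), timestamp_s=ts, label="baseline"))
    for i in range(n_post):
        ts = (i + 1) * sweep_interval_s
        trace = _render_sweep([stim], [amp * potentiation_factor], params, noise_sd, rng)
        sweeps.append(FepspSweep(trace, params["fs_hz"], (stim,), timestamp_s=ts, label="post"))
    for isi_ms, factor in sorted(ppr_factors.items()):
        stim2 = stim + float(isi_ms) / 1000.0
        trace = _render_sweep([stim, stim2], [amp, amp * factor], params, noise_sd, rng)
        sweeps.append(
            FepspSweep(trace, params["fs_hz"], (stim, stim2), timestamp_s=0.0, label=f"ppr_{isi_ms}")
        )
    max_slope = amp * _kernel_max_slope(params["tau_rise_s"], params["tau_decay_s"], params["fs_hz"])
    truth = GroundTruth(
        max_slope_mv_per_ms=max_slope,
        potentiation_factor=potentiation_factor,
        ppr_factors={float(k): v for k, v in ppr_factors.items()},
    )
    return sweeps, truth


def simulate_io_sweeps(
    intensities_ua: Sequence[float] = tuple(range(20, 121, 10)),
    saturation_ua: float = 80.0,
    threshold_ua: float = 15.0,
    max_amplitude_mv: float = 1.5,
    sweep_params: dict | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[list[FepspSweep], GroundTruth]:
    """Input-output sweep set: response amplitude saturates with intensity."""
    params = dict(DEFAULT_SWEEP_PARAMS)
    if sweep_params:
        params.update(sweep_params)
    rng = _rng(seed, "fepsp")
    stim = params["pre_stim_s"]
    sweeps = []
    true_amps = {}
    for ua in intensities_ua:
        drive = max(0.0, ua - threshold_ua)
        amp = max_amplitude_mv * drive / (drive + (saturation_ua - threshold_ua))
        true_amps[float(ua)] = amp
        for r in range(n_replicates):
            trace = _render_sweep([stim], [amp], params, noise_sd, rng)
            sweeps.append(
                FepspSweep(trace, params["fs_hz"], (stim,), stim_intensity_ua=float(ua),
                           timestamp_s=float(r), label="io")
            )
    slope_unit = _kernel_max_slope(params["tau_rise_s"], params["tau_decay_s"], params["fs_hz"])
    truth = GroundTruth(extra={"true_amplitudes_mv": true_amps,
                               "kernel_max_slope_per_mv": slope_unit})
    return sweeps, truth


# ---------------------------------------------------------------------------
# Spines

SPINE_CLASSES = ("filopodia", "long_thin", "thin", "stubby", "mushroom", "branched")

# (length range, width range, heads); ranges keep a margin from every
# decision boundary of the classifier so jitter cannot flip the class.
_CLASS_REGIONS = {
    "branched": ((0.5, 1.8), (0.2, 0.55), 2),
    "filopodia": ((2.2, 3.5), (0.1, 0.5), 1),
    "mushroom": ((0.8, 1.8), (0.7, 1.2), 1),
    "stubby": ((0.25, 0.5), (0.45, 0.58), 1),  # length < width => ratio < 1
    "thin": ((0.5, 0.9), (0.15, 0.4), 1),
    "long_thin": ((1.1, 1.9), (0.2, 0.55), 1),
}
_JITTER_MARGIN_UM = 0.05


def simulate_spines(n_per_class: dict, jitter: float = 0.0, seed: int = 0):
    """Table of spine geometries drawn strictly inside each class region.

    Returns a pandas DataFrame with columns length_um, width_um, heads,
    true_class.  ``jitter`` (μm, uniform, at most the safety margin) is
    added after sampling from a shrunk region, so the true class always
    matches the classifier's decision region.
    """
    import pandas as pd

    if jitter < 0 or jitter > _JITTER_MARGIN_UM:
        raise ValueError(f"jitter must be in [0, {_JITTER_MARGIN_UM}] μm")
    rng = _rng(seed, "spines")
    rows = []
    for cls in SPINE_CLASSES:
        count = int(n_per_class.get(cls, 0))
        if count < 0:
            raise ValueError("counts must be nonnegative")
        (l_lo, l_hi), (w_lo, w_hi), heads = _CLASS_REGIONS[cls]
        for _ in range(count):
            length = rng.uniform(l_lo + jitter, l_hi - jitter)
            width = rng.uniform(w_lo + jitter, w_hi - jitter)
            if cls == "stubby":
                # keep the ratio strictly below 1 even after jitter
                length = width * rng.uniform(0.5, 0.85)
            if jitter > 0:
                length += rng.uniform(-jitter, jitter)
                width += rng.uniform(-jitter, jitter)
            rows.append({"length_um": length, "width_um": width,
                         "heads": heads, "true_class": cls})
    return pd.DataFrame(rows, columns=["length_um", "width_um", "heads", "true_class"])


def simulate_segment(
    density_per_um: float,
    segment_length_um: float = 50.0,
    class_mix: dict | None = None,
    jitter: float = 0.0,
    seed: int = 0,
):
    """One dendritic segment at an exact target density.

    ``round(density * length)`` spines are drawn according to
    ``class_mix`` proportions (default: uniform over the six classes).
    Returns ``(spine_table, segment_length_um)``.
    """
    n_total = int(round(density_per_um * segment_length_um))
    mix = class_mix or {c: 1.0 for c in SPINE_CLASSES}
    total_w = sum(mix.values())
    counts = {c: int(round(n_total * w / total_w)) for c, w in mix.items()}
    drift = n_total - sum(counts.values())
    if drift != 0 and counts:
        first = next(iter(counts))
        counts[first] += drift
    table = simulate_spines(counts, jitter=jitter, seed=seed)
    return table, segment_length_um


# ---------------------------------------------------------------------------
# Puncta images

DEFAULT_COLOC_RADIUS_UM = 0.5


def _stamp_gaussian(img: np.ndarray, cy: float, cx: float, sigma_px: float, amp: float) -> None:
    rad = int(np.ceil(4 * sigma_px))
    y0, y1 = int(np.floor(cy)) - rad, int(np.floor(cy)) + rad + 1
    x0, x1 = int(np.floor(cx)) - rad, int(np.floor(cx)) + rad + 1
    y0c, x0c = max(y0, 0), max(x0, 0)
    y1c, x1c = min(y1, img.shape[0]), min(x1, img.shape[1])
    if y0c >= y1c or x0c >= x1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    img[y0c:y1c, x0c:x1c] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2)
    )


def simulate_puncta_image(
    field_um: float,
    px_size_um: float,
    n_puncta_a: int,
    n_puncta_b: int,
    coloc_fraction: float,
    psf_sigma_um: float = 0.15,
    seed: int = 0,
    coloc_radius_um: float = DEFAULT_COLOC_RADIUS_UM,
    amplitude: float = 100.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Two-channel Gaussian-spot field with a set colocalized fraction.

    Exactly ``round(coloc_fraction * n_puncta_a)`` channel-A puncta get
    a channel-B partner within ``coloc_radius_um``; every other punctum
    of either channel is kept farther than twice that radius from all
    opposite-channel puncta.  Returns ``(image[2, H, W], truth)``.
    """
    if not 0 <= coloc_fraction <= 1:
        raise ValueError("coloc_fraction must be in [0, 1]")
    if n_puncta_b < int(round(coloc_fraction * n_puncta_a)):
        raise ValueError("n_puncta_b too small for requested coloc_fraction")
    rng = _rng(seed, "puncta")
    npx = int(round(field_um / px_size_um))
    img = np.zeros((2, npx, npx), dtype=np.float64)
    margin = 4 * coloc_radius_um
    min_sep = 4 * coloc_radius_um  # same-channel spacing keeps matching unambiguous

    def _draw_separated(n: int, existing: list) -> list[np.ndarray]:
        pts: list[np.ndarray] = []
        attempts = 0
        while len(pts) < n:
            attempts += 1
            if attempts > 20_000 * max(n, 1):
                raise RuntimeError("field too dense for requested punctum count")
            p = rng.uniform(margin, field_um - margin, 2)
            if all(np.linalg.norm(p - q) >= min_sep for q in pts + existing):
                pts.append(p)
        return pts

    a_pts = _draw_separated(n_puncta_a, [])
    n_pairs = int(round(coloc_fraction * n_puncta_a))
    b_pts: list[np.ndarray] = []
    for p in a_pts[:n_pairs]:
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0, 0.5 * coloc_radius_um)
        b_pts.append(p + dist * np.array([np.cos(ang), np.sin(ang)]))
    # unpaired B puncta: away from every A punctum and from paired Bs
    n_free = n_puncta_b - n_pairs
    free_pts: list[np.ndarray] = []
    attempts = 0
    while len(free_pts) < n_free:
        attempts += 1
        if attempts > 20_000 * max(n_free, 1):
            raise RuntimeError("field too dense for requested punctum count")
        p = rng.uniform(margin, field_um - margin, 2)
        if all(np.linalg.norm(p - q) > 2 * coloc_radius_um for q in a_pts) and all(
            np.linalg.norm(p - q) >= min_sep for q in b_pts + free_pts
        ):
            free_pts.append(p)
    b_pts = b_pts + free_pts

    sigma_px = psf_sigma_um / px_size_um
    for p in a_pts:
        _stamp_gaussian(img[0], p[0] / px_size_um, p[1] / px_size_um, sigma_px, amplitude)
    for p in b_pts:
        _stamp_gaussian(img[1], p[0] / px_size_um, p[1] / px_size_um, sigma_px, amplitude)

    truth = GroundTruth(
        coloc_pairs=n_pairs,
        extra={
            "a_centroids_um": np.array(a_pts).reshape(-1, 2),
            "b_centroids_um": np.array(b_pts).reshape(-1, 2),
            "coloc_radius_um": coloc_radius_um,
        },
    )
    return img, truth
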