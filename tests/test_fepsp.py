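import numpy as np
import pandas as pd
import pytest

from hipposlice.fepsp import (
    SlopeConfig,
    fepsp_slope,
    half_max_intensity,
    io_curve,
    ltp_normalize,
    ltp_summary,
    paired_pulse_ratio,
)
from hipposlice.simulate import (
    DEFAULT_SWEEP_PARAMS,
    FepspSweep,
    PPR_ISIS_MS,
    epsp_kernel,
    simulate_fepsp_series,
    simulate_io_sweeps,
)


def ramp_sweep(slope_mv_per_ms, fs=10_000.0, duration_s=0.1, stim_s=0.01):
    """Negative-going linear ramp starting 2 ms after the stimulus."""
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    onset = stim_s + 0.002
    trace = np.where(t >= onset, -(t - onset) * 1000.0 * slope_mv_per_ms, 0.0)
    trace = np.clip(trace, -slope_mv_per_ms * 20.0, None)  # plateau at 20 ms depth
    return FepspSweep(trace, fs, (stim_s,))


class TestFepspSlope:
    def test_linear_ramp_exact(self):
        sweep = ramp_sweep(0.8)
        slope, flagged = fepsp_slope(sweep)
        assert not flagged
        assert slope == pytest.approx(0.8, rel=1e-6)

    def test_alpha_function_vs_finite_difference_oracle(self):
        # oracle: finite-difference chord over the same 20-80% span of
        # the noiseless alpha-function rising phase
        fs, tau, amp, stim = 10_000.0, 0.003, 1.2, 0.01
        n = int(0.1 * fs)
        t = np.arange(n) / fs
        rel = np.clip(t - (stim + 0.002), 0, None)
        alpha = np.where(rel > 0, amp * (rel / tau) * np.exp(1 - rel / tau), 0.0)
        sweep = FepspSweep(-alpha, fs, (stim,))
        slope, flagged = fepsp_slope(sweep)
        assert not flagged

        tf = np.linspace(0, 5 * tau, 100_000)
        yf = amp * (tf / tau) * np.exp(1 - tf / tau)
        t20 = tf[np.argmin(np.abs(yf[: np.argmax(yf)] - 0.2 * amp))]
        t80 = tf[np.argmin(np.abs(yf[: np.argmax(yf)] - 0.8 * amp))]
        oracle = (0.8 * amp - 0.2 * amp) / ((t80 - t20) * 1000.0)
        assert slope == pytest.approx(oracle, rel=0.10)

    def test_no_response_flagged_zero(self):
        sweep = FepspSweep(np.zeros(1000), 10_000.0, (0.01,))
        slope, flagged = fepsp_slope(sweep)
        assert slope == 0.0 and flagged


class TestIoCurve:
    def test_identity_aggregation(self):
        sweeps = [ramp_sweep(0.5)]
        sweeps[0] = FepspSweep(sweeps[0].trace_mv, sweeps[0].fs_hz,
                               sweeps[0].stim_times_s, stim_intensity_ua=40.0)
        curve = io_curve(sweeps)
        assert len(curve) == 1
        assert curve.iloc[0]["mean_slope_mv_per_ms"] == pytest.approx(0.5, rel=1e-6)

    def test_eleven_intensities(self):
        sweeps, _ = simulate_io_sweeps(noise_sd=0.0)
        curve = io_curve(sweeps)
        assert len(curve) == 11
        np.testing.assert_array_equal(curve["intensity_ua"], np.arange(20, 121, 10))

    def test_noiseless_curve_monotone(self):
        sweeps, _ = simulate_io_sweeps(noise_sd=0.0)
        curve = io_curve(sweeps)
        assert np.all(np.diff(curve["mean_slope_mv_per_ms"]) >= -1e-9)

    def test_replicated_noisy_sweeps_recover_truth(self):
        sweeps, truth = simulate_io_sweeps(noise_sd=0.005, n_replicates=8, seed=3)
        curve = io_curve(sweeps)
        for row in curve.itertuples():
            true_amp = truth.extra["true_amplitudes_mv"][row.intensity_ua]
            if true_amp < 0.3:  # slope fit is noise-limited for tiny responses
                continue
            # mean within 4 SEM (plus fit tolerance) of the noiseless slope
            ref_sweep, _ = simulate_io_sweeps(
                intensities_ua=[row.intensity_ua], noise_sd=0.0)
            ref_slope = io_curve(ref_sweep[0:1]).iloc[0]["mean_slope_mv_per_ms"]
            tol = max(4 * (row.sem_slope_mv_per_ms or 0), 0.03 * ref_slope)
            assert abs(row.mean_slope_mv_per_ms - ref_slope) <= tol


class TestHalfMax:
    def test_linear_curve_midpoint(self):
        curve = pd.DataFrame({
            "intensity_ua": np.arange(20, 121, 10),
            "mean_slope_mv_per_ms": np.linspace(0, 1, 11),
        })
        ua, degenerate = half_max_intensity(curve)
        assert ua == 70.0 and not degenerate

    def test_saturating_curve_matches_grid_oracle(self):
        sweeps, truth = simulate_io_sweeps(noise_sd=0.0)
        curve = io_curve(sweeps)
        ua, _ = half_max_intensity(curve)
        # oracle: brute-force grid search on the generator's true amplitudes
        amps = truth.extra["true_amplitudes_mv"]
        target = 0.5 * max(amps.values())
        oracle = min(amps, key=lambda k: (abs(amps[k] - target), k))
        assert ua == oracle

    def test_all_equal_flagged_degenerate(self):
        curve = pd.DataFrame({"intensity_ua": [20.0, 40.0, 60.0],
                              "mean_slope_mv_per_ms": [1.0, 1.0, 1.0]})
        ua, degenerate = half_max_intensity(curve)
        assert ua == 20.0 and degenerate

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError):
            half_max_intensity(pd.DataFrame(columns=["intensity_ua",
                                                     "mean_slope_mv_per_ms"]))


class TestPairedPulse:
    def test_self_paired_identity(self):
        # a sweep whose second response duplicates the first bit-for-bit
        sweeps, _ = simulate_fepsp_series(1, 0, noise_sd=0.0, seed=0)
        single = sweeps[0]
        shift = int(round(0.2 * single.fs_hz))
        base = single.trace_mv.copy()
        base[int(round(0.18 * single.fs_hz)) :] = 0.0  # drop the ~1e-11 tail
        trace = base.copy()
        trace[shift:] += base[:-shift]
        paired = FepspSweep(trace, single.fs_hz,
                            (single.stim_times_s[0], single.stim_times_s[0] + 0.2))
        ratio, flagged = paired_pulse_ratio(paired)
        assert not flagged
        assert ratio == 1.0

    def test_generator_unity_factor(self):
        sweeps, _ = simulate_fepsp_series(0, 0, ppr_factors_per_isi={200.0: 1.0},
                                          noise_sd=0.0, seed=0)
        ratio, flagged = paired_pulse_ratio(sweeps[0])
        assert not flagged
        assert ratio == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("isi_ms", PPR_ISIS_MS)
    @pytest.mark.parametrize("factor", [1.0, 1.5])
    def test_facilitation_recovery_noiseless(self, isi_ms, factor):
        sweeps, _ = simulate_fepsp_series(
            0, 0, ppr_factors_per_isi={isi_ms: factor}, noise_sd=0.0, seed=0)
        ratio, flagged = paired_pulse_ratio(sweeps[0])
        assert not flagged
        assert ratio == pytest.approx(factor, rel=0.05)

    def test_rejects_off_protocol_isi(self):
        params = DEFAULT_SWEEP_PARAMS
        n = int(params["sweep_duration_s"] * params["fs_hz"])
        sweep = FepspSweep(np.zeros(n), params["fs_hz"], (0.01, 0.045))
        with pytest.raises(ValueError):
            paired_pulse_ratio(sweep)

    def test_zero_first_slope_flagged(self):
        n = 3000
        sweep = FepspSweep(np.zeros(n), 10_000.0, (0.01, 0.21))
        ratio, flagged = paired_pulse_ratio(sweep)
        assert ratio is None and flagged

    def test_rejects_single_stimulus(self):
        sweep = ramp_sweep(0.5)
        with pytest.raises(ValueError):
            paired_pulse_ratio(sweep)


class TestLtp:
    def test_constant_slopes_flat_100(self):
        sweeps, _ = simulate_fepsp_series(10, 10, potentiation_factor=1.0,
                                          noise_sd=0.0, seed=0)
        series = ltp_normalize(sweeps, hfs_time_s=0.0, baseline_min=6.0)
        np.testing.assert_allclose(series.normalized_slope_pct, 100.0, rtol=1e-9)

    def test_step_potentiation(self):
        sweeps, _ = simulate_fepsp_series(10, 10, potentiation_factor=1.5,
                                          noise_sd=0.0, seed=0)
        series = ltp_normalize(sweeps, hfs_time_s=0.0, baseline_min=6.0)
        post = series.normalized_slope_pct[series.times_min > 0]
        assert np.mean(post) == pytest.approx(150.0, rel=1e-6)

    def test_baseline_mean_is_100(self):
        sweeps, _ = simulate_fepsp_series(8, 8, potentiation_factor=1.3,
                                          noise_sd=0.02, seed=1)
        series = ltp_normalize(sweeps, hfs_time_s=0.0, baseline_min=5.0)
        base = series.normalized_slope_pct[(series.times_min < 0)
                                           & (series.times_min >= -5.0)]
        assert base.mean() == pytest.approx(100.0, rel=1e-9)

    def test_scaling_invariance(self):
        sweeps, _ = simulate_fepsp_series(5, 5, potentiation_factor=1.4,
                                          noise_sd=0.0, seed=2)
        series = ltp_normalize(sweeps, hfs_time_s=0.0, baseline_min=4.0)
        scaled = [FepspSweep(3.0 * s.trace_mv, s.fs_hz, s.stim_times_s,
                             timestamp_s=s.timestamp_s) for s in sweeps]
        series2 = ltp_normalize(scaled, hfs_time_s=0.0, baseline_min=4.0)
        np.testing.assert_allclose(series2.normalized_slope_pct,
                                   series.normalized_slope_pct, rtol=1e-9)

    def test_no_baseline_errors(self):
        sweeps, _ = simulate_fepsp_series(0, 5, seed=0)
        with pytest.raises(ValueError):
            ltp_normalize(sweeps, hfs_time_s=0.0)


class TestLtpSummary:
    def _series(self, factor, noise_sd, n_post=20, seed=0):
        sweeps, _ = simulate_fepsp_series(10, n_post, potentiation_factor=factor,
                                          noise_sd=noise_sd, seed=seed)
        return ltp_normalize(sweeps, hfs_time_s=0.0, baseline_min=6.0)

    def test_flat_series(self):
        series = self._series(1.0, 0.0)
        summary = ltp_summary(series)
        assert summary["mean_pct"] == pytest.approx(100.0, rel=1e-9)
        assert summary["sem_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_plateau_recovery_within_sem(self):
        series = self._series(1.5, 0.02, seed=5)
        summary = ltp_summary(series)
        assert abs(summary["mean_pct"] - 150.0) <= max(2 * summary["sem_pct"], 3.0)

    def test_ordered_parameter_recovery(self):
        # factors {1.0, 1.2, 1.5, 2.0}: ordered and each within 5%
        means = []
        for factor in (1.0, 1.2, 1.5, 2.0):
            summary = ltp_summary(self._series(factor, 0.02, seed=7))
            means.append(summary["mean_pct"])
            assert summary["mean_pct"] == pytest.approx(100.0 * factor, rel=0.05)
        assert means == sorted(means)

    def test_empty_final_window_errors(self):
        sweeps, _ = simulate_fepsp_series(5, 0, seed=0)
        series_sweeps = sweeps  # no post-HFS sweeps at all
        with pytest.raises(ValueError):
            series = ltp_normalize(series_sweeps, hfs_time_s=0.0, baseline_min=4.0)
            ltp_summary(series)
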