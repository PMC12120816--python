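"""Normality-gated two-group comparison and the end-to-end synthetic pipeline.

Two-group endpoints are compared with a Student's t-test when both
samples pass Shapiro-Wilk normality at alpha, and with a Mann-Whitney U
test otherwise.  ``run_pipeline`` wires the generators and quantifiers
into a two-cohort comparison with deterministic seeding.

Note: the simple > k·MAD outlier flagging offered here is NOT the ROUT
procedure and is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import fepsp as fepsp_mod
from . import gamma as gamma_mod
from . import io as io_mod
from . import morphometry as morph
from . import simulate as sim
from . import swr as swr_mod
from .signal_core import power_spectrum

__all__ = ["GroupComparison", "compare_groups", "mad_outlier_flags",
           "run_pipeline", "load_config", "DEFAULT_PIPELINE_CONFIG"]

logger = logging.getLogger("hipposlice")


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    chosen_test: str  # {"t_test", "mann_whitney"}
    statistic: float
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__} | {
            "significant": self.significant
        }


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def compare_groups(
    a, b, alpha: float = 0.05, label_a: str = "a", label_b: str = "b"
) -> GroupComparison:
    """Shapiro-Wilk-gated two-sided two-group comparison.

    Both samples normal at ``alpha`` → two-sample t-test; otherwise
    Mann-Whitney U.  Samples need n >= 3 for the normality test.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    # Shapiro is undefined for constant samples; treat them as non-normal
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        p_a = p_b = 0.0
    else:
        p_a = float(stats.shapiro(a).pvalue)
        p_b = float(stats.shapiro(b).pvalue)
    if p_a > alpha and p_b > alpha:
        res = stats.ttest_ind(a, b)
        chosen = "t_test"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        chosen = "mann_whitney"
    return GroupComparison(
        label_a=label_a, label_b=label_b, n_a=a.size, n_b=b.size,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=_sem(a), sem_b=_sem(b),
        shapiro_p_a=p_a, shapiro_p_b=p_b,
        chosen_test=chosen, statistic=float(res.statistic),
        p_value=float(res.pvalue), alpha=alpha,
    )


def mad_outlier_flags(x, k: float = 3.0) -> np.ndarray:
    """Flag points more than k scaled MADs from the median (not ROUT)."""
    x = np.asarray(x, dtype=np.float64)
    mad = stats.median_abs_deviation(x, scale="normal")
    if mad == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - np.median(x)) > k * mad


# ---------------------------------------------------------------------------
# End-to-end synthetic cohort pipeline

DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "alpha": 0.05,
    "groups": {
        "wt": {},
        "ko": {},
    },
    "lfp": {
        "n_slices": 6,
        "duration_s": 20.0,
        "fs_hz": 2000.0,
        "sw_rate_hz": 0.4,
        "sw_amplitude_mv": 0.3,
        "noise_amplitude_mv": 0.05,
        "ripple_freq_hz": 200.0,
        "ripple_amplitude_mv": 0.1,
    },
    "gamma": {
        "n_slices": 6,
        "duration_s": 20.0,
        "fs_hz": 2000.0,
        "osc_freq_hz": 40.0,
        "osc_amplitude_mv": 0.05,
        "noise_amplitude_mv": 0.02,
    },
    "spines": {
        "n_animals": 6,
        "density_per_um": 0.5,
        "density_jitter": 0.1,
        "segment_um": 50.0,
    },
    "ltp": {
        "n_slices": 6,
        "n_baseline": 10,
        "n_post": 20,
        "potentiation_factor": 1.5,
        "noise_sd": 0.02,
    },
}


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    merged = _deep_merge(DEFAULT_PIPELINE_CONFIG, cfg or {})
    _validate_config(merged)
    return merged


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _validate_config(cfg: dict) -> None:
    if not cfg.get("groups"):
        raise ValueError("pipeline config must define at least two groups")
    if len(cfg["groups"]) < 2:
        raise ValueError("pipeline needs two groups to compare")
    for section in ("lfp", "gamma", "spines", "ltp"):
        if section in cfg and cfg[section].get("n_slices", cfg[section].get("n_animals", 1)) < 1:
            raise ValueError(f"{section}: cohort size must be >= 1")


def _group_seed(seed: int, group_index: int, unit: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, group_index, unit, stage]).generate_state(1)[0])


def _lfp_endpoints(cfg: dict, group_cfg: dict, seed: int, gi: int) -> dict:
    p = {**cfg["lfp"], **group_cfg.get("lfp", {})}
    incidences, areas = [], []
    for s in range(int(p["n_slices"])):
        config = sim.LfpSimConfig(
            duration_s=p["duration_s"], fs_hz=p["fs_hz"], sw_rate_hz=p["sw_rate_hz"],
            sw_amplitude_mv=p["sw_amplitude_mv"], noise_amplitude_mv=p["noise_amplitude_mv"],
            ripple_freq_hz=p["ripple_freq_hz"], ripple_amplitude_mv=p["ripple_amplitude_mv"],
            seed=_group_seed(seed, gi, s, 0),
        )
        rec, _ = sim.simulate_lfp(config)
        events = swr_mod.detect_and_quantify(rec)
        summary = swr_mod.swr_summary(events, rec.duration_s)
        incidences.append(summary["incidence_per_s"])
        areas.append(summary["mean_sw_area_mv_ms"] or 0.0)
    return {"swr_incidence_per_s": incidences, "sw_area_mv_ms": areas}


def _gamma_endpoints(cfg: dict, group_cfg: dict, seed: int, gi: int) -> dict:
    p = {**cfg["gamma"], **group_cfg.get("gamma", {})}
    powers, freqs = [], []
    for s in range(int(p["n_slices"])):
        rec, _ = sim.simulate_gamma(
            p["duration_s"], p["fs_hz"], p["osc_freq_hz"], p["osc_amplitude_mv"],
            p["noise_amplitude_mv"], seed=_group_seed(seed, gi, s, 1),
        )
        metrics = gamma_mod.apply_exclusion(gamma_mod.gamma_metrics(power_spectrum(rec)))
        if metrics.excluded:
            continue
        powers.append(metrics.integrated_power_mv2)
        freqs.append(metrics.peak_frequency_hz)
    return {"gamma_integrated_power_mv2": powers, "gamma_peak_freq_hz": freqs}


def _spine_endpoints(cfg: dict, group_cfg: dict, seed: int, gi: int) -> dict:
    p = {**cfg["spines"], **group_cfg.get("spines", {})}
    densities = []
    for a in range(int(p["n_animals"])):
        rng = np.random.default_rng(_group_seed(seed, gi, a, 2))
        density = p["density_per_um"] * float(rng.normal(1.0, p["density_jitter"]))
        density = max(density, 0.02)
        table, seg_len = sim.simulate_segment(
            density, p["segment_um"], seed=_group_seed(seed, gi, a, 3)
        )
        table = morph.classify_table(table)
        spines = [
            morph.SpineRecord(r.length_um, r.width_um, int(r.heads))
            for r in table.itertuples()
        ]
        seg = morph.DendriteSegment(length_um=seg_len, spines=spines)
        densities.append(morph.spine_density(seg)["density_per_50um"])
    return {"spine_density_per_50um": densities}


def _ltp_endpoints(cfg: dict, group_cfg: dict, seed: int, gi: int) -> dict:
    p = {**cfg["ltp"], **group_cfg.get("ltp", {})}
    plateaus = []
    for s in range(int(p["n_slices"])):
        sweeps, _ = sim.simulate_fepsp_series(
            n_baseline=int(p["n_baseline"]), n_post=int(p["n_post"]),
            potentiation_factor=p["potentiation_factor"], noise_sd=p["noise_sd"],
            seed=_group_seed(seed, gi, s, 4),
        )
        series = fepsp_mod.ltp_normalize(sweeps, hfs_time_s=0.0,
                                         baseline_min=p["n_baseline"] * 30.0 / 60.0 + 1)
        plateaus.append(fepsp_mod.ltp_summary(series)["mean_pct"])
    return {"ltp_last10_pct": plateaus}


_STAGES = {
    "lfp": _lfp_endpoints,
    "gamma": _gamma_endpoints,
    "spines": _spine_endpoints,
    "ltp": _ltp_endpoints,
}


def run_pipeline(config: dict, out_dir: str | Path | None = None,
                 stages: tuple = ("lfp", "gamma", "spines", "ltp")) -> dict:
    """Simulate → quantify → aggregate → compare for a two-group cohort.

    Returns a bundle with per-endpoint samples and group comparisons;
    when ``out_dir`` is given, writes manifest.json, one CSV per
    endpoint, and a markdown summary.
    """
    _validate_config(config)
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    group_names = list(config["groups"])
    endpoints: dict[str, dict[str, list]] = {}
    for gi, name in enumerate(group_names):
        group_cfg = config["groups"][name] or {}
        for stage in stages:
            vals = _STAGES[stage](config, group_cfg, seed, gi)
            for key, sample in vals.items():
                endpoints.setdefault(key, {})[name] = sample

    comparisons = {}
    ga, gb = group_names[:2]
    for key, samples in endpoints.items():
        va, vb = samples.get(ga, []), samples.get(gb, [])
        if len(va) < 3 or len(vb) < 3:
            logger.warning("endpoint %s skipped: too few values", key)
            continue
        comparisons[key] = compare_groups(va, vb, alpha=alpha, label_a=ga, label_b=gb)

    bundle = {
        "seed": seed,
        "alpha": alpha,
        "groups": group_names,
        "endpoints": endpoints,
        "comparisons": {k: c.to_dict() for k, c in comparisons.items()},
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io_mod.write_json({k: v for k, v in bundle.items() if k != "endpoints"},
                      out_dir / "manifest.json")
    for key, samples in bundle["endpoints"].items():
        rows = [{"group": g, "value": v} for g, vals in samples.items() for v in vals]
        pd.DataFrame(rows).to_csv(out_dir / f"{key}.csv", index=False)
    lines = ["# Synthetic cohort comparison", ""]
    for key, c in bundle["comparisons"].items():
        mark = "*" if c["significant"] else "n/s"
        lines.append(
            f"- **{key}**: {c['label_a']} {c['mean_a']:.4g}±{c['sem_a']:.2g} vs "
            f"{c['label_b']} {c['mean_b']:.4g}±{c['sem_b']:.2g}; "
            f"{c['chosen_test']} p={c['p_value']:.3g} ({mark})"
        )
    (out_dir / "summary.md").write_text("\n".join(lines) + "\n")
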