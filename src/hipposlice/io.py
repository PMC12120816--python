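"""Readers and writers for the formats the pipeline exchanges.

LFP traces travel as two-column CSV (time_s, mv) or raw little-endian
float32 with a JSON sidecar carrying the sampling metadata; spectra and
correlograms as CSV; ground truth and metrics as JSON; images as
multi-page TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .signal_core import LfpRecording, Spectrum

__all__ = [
    "write_lfp_csv",
    "read_lfp_csv",
    "write_lfp_binary",
    "read_lfp_binary",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_correlogram_csv",
    "write_json",
    "read_json",
    "write_image_tiff",
    "read_image_tiff",
]


def write_lfp_csv(rec: LfpRecording, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": rec.times_s, "mv": rec.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def read_lfp_csv(path: str | Path, label: str = "") -> LfpRecording:
    df = pd.read_csv(path)
    if not {"time_s", "mv"} <= set(df.columns):
        raise ValueError("LFP CSV needs columns time_s, mv")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time column must be uniformly increasing")
    return LfpRecording(samples=df["mv"].to_numpy(), fs_hz=1.0 / float(dt[0]),
                        t0_s=float(t[0]), label=label or str(path))


def write_lfp_binary(rec: LfpRecording, path: str | Path) -> None:
    """Raw little-endian float32 samples plus a JSON sidecar."""
    path = Path(path)
    rec.samples.astype("<f4").tofile(path)
    sidecar = {"fs_hz": rec.fs_hz, "units": "mV", "duration_s": rec.duration_s,
               "t0_s": rec.t0_s, "n_samples": rec.n_samples}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_lfp_binary(path: str | Path, label: str = "") -> LfpRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    samples = np.fromfile(path, dtype="<f4").astype(np.float64)
    if samples.size != sidecar["n_samples"]:
        raise ValueError("sample count disagrees with sidecar")
    return LfpRecording(samples=samples, fs_hz=sidecar["fs_hz"],
                        t0_s=sidecar.get("t0_s", 0.0), label=label or str(path))


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"freq_hz": spec.freqs_hz, "power_mv2": spec.power_mv2}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_spectrum_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    freqs = df["freq_hz"].to_numpy()
    res = float(freqs[1] - freqs[0]) if freqs.size > 1 else 1.0
    return Spectrum(freqs_hz=freqs, power_mv2=df["power_mv2"].to_numpy(), resolution_hz=res)


def write_correlogram_csv(lags_s: np.ndarray, coeffs: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"lag_s": lags_s, "coefficient": coeffs}).to_csv(
        path, index=False, float_format="%.9g"
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def write_image_tiff(image: np.ndarray, path: str | Path) -> None:
    """Multi-page TIFF, one page per channel."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float64)
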