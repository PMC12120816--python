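"""Spine classification and density, ROI intensity, puncta colocalization.

Spines are assigned to one of six classes by a fixed-precedence rule
sequence (branched, filopodia, mushroom, stubby, thin, long-thin);
the printed inequalities overlap, so first-match-wins precedence keeps
the decision regions a partition.  Densities are reported per 50 μm of
dendrite and aggregated segment → neuron → animal by unweighted means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .simulate import SPINE_CLASSES

__all__ = [
    "SpineRecord",
    "DendriteSegment",
    "RoiSpec",
    "PunctaSet",
    "classify_spine",
    "classify_table",
    "spine_density",
    "aggregate_hierarchy",
    "roi_mean_intensity",
    "detect_puncta",
    "colocalize",
]

DEFAULT_SEGMENT_UM = 50.0
FILOPODIA_MIN_LENGTH_UM = 2.0
THIN_MAX_LENGTH_UM = 1.0
MUSHROOM_MIN_WIDTH_UM = 0.6
MIN_BRANCHED_HEADS = 2


def classify_spine(length_um: float, width_um: float, heads: int = 1) -> str:
    """Morphological class of one spine; first matching rule wins.

    Order: branched (>= 2 heads), filopodia (length > 2 μm), mushroom
    (width > 0.6 μm), stubby (length:width < 1), thin (length < 1 μm),
    long-thin (otherwise, i.e. length in [1, 2] μm).
    """
    if length_um <= 0 or width_um <= 0:
        raise ValueError("length and width must be positive")
    if heads < 1:
        raise ValueError("heads must be >= 1")
    if heads >= MIN_BRANCHED_HEADS:
        return "branched"
    if length_um > FILOPODIA_MIN_LENGTH_UM:
        return "filopodia"
    if width_um > MUSHROOM_MIN_WIDTH_UM:
        return "mushroom"
    if length_um / width_um < 1.0:
        return "stubby"
    if length_um < THIN_MAX_LENGTH_UM:
        return "thin"
    return "long_thin"


@dataclass(frozen=True)
class SpineRecord:
    length_um: float
    width_um: float
    heads: int = 1
    thorny_flag: bool = False  # manual label, passed through, never inferred
    assigned_class: str = ""

    def __post_init__(self) -> None:
        if not self.assigned_class:
            object.__setattr__(
                self, "assigned_class", classify_spine(self.length_um, self.width_um, self.heads)
            )
        elif self.assigned_class not in SPINE_CLASSES:
            raise ValueError(f"unknown class {self.assigned_class!r}")


@dataclass
class DendriteSegment:
    length_um: float
    spines: list = field(default_factory=list)
    region: str = ""

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("segment length must be positive")


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add an ``assigned_class`` column to a (length_um, width_um, heads) table."""
    out = table.copy()
    out["assigned_class"] = [
        classify_spine(r.length_um, r.width_um, int(getattr(r, "heads", 1)))
        for r in table.itertuples()
    ]
    return out


def spine_density(segment: DendriteSegment, per_um: float = DEFAULT_SEGMENT_UM) -> dict:
    """Spine count normalized to ``per_um`` of dendrite, plus class mix."""
    n = len(segment.spines)
    density = n * per_um / segment.length_um
    if n == 0:
        return {"density_per_50um": density, "composition": None, "n_spines": 0,
                "thorny_count": 0}
    classes = [s.assigned_class for s in segment.spines]
    composition = {c: classes.count(c) / n for c in SPINE_CLASSES}
    thorny = sum(1 for s in segment.spines if s.thorny_flag)
    return {"density_per_50um": density, "composition": composition, "n_spines": n,
            "thorny_count": thorny}


def aggregate_hierarchy(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Per-animal means via unweighted two-level averaging.

    ``table`` needs columns animal, neuron and ``value`` (one row per
    segment).  Segment values are averaged within each neuron, then
    neuron means within each animal — neurons with unequal segment
    counts are weighted equally.
    """
    for col in ("animal", "neuron", value):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    neuron_means = table.groupby(["animal", "neuron"], sort=True)[value].mean()
    animal_means = neuron_means.groupby("animal").mean()
    return animal_means.reset_index().rename(columns={value: f"mean_{value}"})


@dataclass(frozen=True)
class RoiSpec:
    """Polygon ROI in pixel coordinates (0-based, y-down) with pixel size."""

    polygon_px: np.ndarray  # (n, 2) array of (row, col) vertices
    px_size_um: float

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon_px, dtype=np.float64)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("polygon needs at least 3 (row, col) vertices")
        if self.px_size_um <= 0:
            raise ValueError("pixel size must be positive")
        object.__setattr__(self, "polygon_px", poly)

    def mask(self, shape: tuple) -> np.ndarray:
        return polygon2mask(shape, self.polygon_px)


def roi_mean_intensity(image: np.ndarray, roi: RoiSpec) -> float:
    """Average intensity per μm²: pixel sum inside the ROI over its μm² area."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if np.any(roi.polygon_px < 0) or np.any(roi.polygon_px[:, 0] > img.shape[0]) or np.any(
        roi.polygon_px[:, 1] > img.shape[1]
    ):
        raise ValueError("ROI polygon exceeds image bounds")
    mask = roi.mask(img.shape)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty ROI")
    area_um2 = n_px * roi.px_size_um**2
    return float(img[mask].sum() / area_um2)


@dataclass
class PunctaSet:
    """Detected puncta: centroids in μm plus per-punctum area and intensity."""

    centroids_um: np.ndarray  # (n, 2)
    areas_um2: np.ndarray
    mean_intensities: np.ndarray

    def __len__(self) -> int:
        return self.centroids_um.shape[0]


def detect_puncta(
    image: np.ndarray,
    px_size_um: float,
    intensity_threshold: float,
    min_area_um2: float = 0.0,
    max_area_um2: float = np.inf,
) -> PunctaSet:
    """Connected components above a global threshold, within an area band."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    labels = cc_label(img > intensity_threshold)
    centroids, areas, intensities = [], [], []
    for prop in regionprops(labels, intensity_image=img):
        area_um2 = prop.area * px_size_um**2
        if not min_area_um2 <= area_um2 <= max_area_um2:
            continue
        centroids.append(np.array(prop.centroid) * px_size_um)
        areas.append(area_um2)
        intensities.append(prop.intensity_mean)
    return PunctaSet(
        centroids_um=np.array(centroids).reshape(-1, 2),
        areas_um2=np.array(areas),
        mean_intensities=np.array(intensities),
    )


def colocalize(
    a: PunctaSet,
    b: PunctaSet,
    max_dist_um: float = 0.5,
    segment_length_um: float = DEFAULT_SEGMENT_UM,
) -> dict:
    """Double-positive puncta per 50 μm via greedy nearest-pair matching.

    Candidate pairs within ``max_dist_um`` are matched in ascending
    distance order, each punctum used at most once; the matched count is
    symmetric in (a, b).
    """
    if max_dist_um <= 0 or segment_length_um <= 0:
        raise ValueError("distances must be positive")
    if len(a) and len(b):
        diff = a.centroids_um[:, None, :] - b.centroids_um[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        ia, ib = np.nonzero(dist <= max_dist_um)
        order = np.argsort(dist[ia, ib], kind="stable")
        used_a: set = set()
        used_b: set = set()
        matches = []
        for k in order:
            i, j = int(ia[k]), int(ib[k])
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            matches.append((i, j, float(dist[i, j])))
    else:
        matches = []
    n = len(matches)
    return {
        "matched_count": n,
        "per_50um": n * DEFAULT_SEGMENT_UM / segment_length_um,
        "pairs": matches,
        "n_a": len(a),
        "n_b": len(b),
    }
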