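"""Slide-level feature bank extracted from a tumor-probability heatmap.

A stitched heatmap is reduced to a fixed, named feature vector with four
families:

* lesion geometry — connected components of the binarized heatmap, measured in
  physical units (mm², mm) and aggregated over lesions by seven moments;
* heatmap texture — intensity and gradient-magnitude statistics over tissue,
  plus grey-level co-occurrence statistics on the quantized heatmap;
* marginal features — Canny edge-pixel count and mean edge gradient;
* bookkeeping — connected-region count and total lesion pixel count.

The vector ordering is frozen (`FEATURE_NAMES`) so feature tables are
column-stable across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage import measure as skmeasure

__all__ = [
    "Heatmap",
    "Lesion",
    "LesionSet",
    "FeatureConfig",
    "FEATURE_NAMES",
    "binarize",
    "extract_lesions",
    "texture_features",
    "marginal_features",
    "feature_vector",
]


@dataclass(frozen=True)
class Heatmap:
    """Per-pixel tumor probability at a known physical resolution.

    Parameters
    ----------
    probs : float array, shape (H, W)
        Tumor probabilities in [0, 1].
    mpp : float
        Microns per pixel; links pixel counts to mm²/mm features.
    slide_id : str
        Provenance identifier.
    """

    probs: np.ndarray
    mpp: float
    slide_id: str = ""

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2:
            raise ValueError("heatmap must be a 2-D raster")
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError("heatmap probabilities must lie in [0, 1]")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class Lesion:
    """One connected component of the binarized heatmap, in physical units."""

    label: int
    area_mm2: float
    perimeter_mm: float
    diameter_mm: float
    eccentricity: float
    extent: float
    solidity: float
    area_px: int
    centroid: tuple[float, float]


@dataclass
class LesionSet:
    lesions: list[Lesion] = field(default_factory=list)
    mpp: float = 0.0

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    def values(self, prop: str) -> np.ndarray:
        return np.array([getattr(l, prop) for l in self.lesions], dtype=np.float64)


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature stage.

    threshold: heatmap binarization cut (default 0.5).
    min_lesion_area_mm2: components smaller than this are treated as noise
        and dropped (default 0.01 mm²).
    perimeter_method: "crofton" (default) or "contour" (marching squares).
    glcm_levels: quantization levels for co-occurrence statistics.
    """

    threshold: float = 0.5
    min_lesion_area_mm2: float = 0.01
    perimeter_method: str = "crofton"
    glcm_levels: int = 32
    canny_sigma: float = 1.0


_GEOM_PROPS = ("area_mm2", "perimeter_mm", "diameter_mm", "eccentricity", "extent", "solidity")
_AGGS = ("max", "min", "mean", "std", "var", "skew", "kurt")
_DIST_STATS = ("max", "min", "mean", "std", "var", "skew", "kurt", "entropy", "energy")
_GLCM_STATS = ("contrast", "dissimilarity", "homogeneity", "correlation", "energy")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"lesion_{p}_{a}" for p in _GEOM_PROPS for a in _AGGS]
    + [f"intensity_{s}" for s in _DIST_STATS]
    + [f"gradient_{s}" for s in _DIST_STATS]
    + [f"glcm_{s}" for s in _GLCM_STATS]
    + ["canny_nonzero", "canny_mean", "region_count", "lesion_pixel_count"]
)


def binarize(heatmap: Heatmap, threshold: float = 0.5) -> np.ndarray:
    """Pixel is lesion iff its probability is >= ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return heatmap.probs >= threshold


def _perimeter_contour(component: np.ndarray) -> float:
    """Marching-squares contour length of one binary component, in px."""
    padded = np.pad(component.astype(float), 1)
    total = 0.0
    for contour in skmeasure.find_contours(padded, 0.5):
        seg = np.diff(contour, axis=0)
        total += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return total


def extract_lesions(
    mask: np.ndarray,
    mpp: float,
    min_area_mm2: float = 0.01,
    perimeter_method: str = "crofton",
) -> LesionSet:
    """Measure 8-connected components of a binary lesion mask.

    Areas convert as ``px * (mpp/1000)**2`` (mm²), lengths as ``px * mpp/1000``
    (mm). Components smaller than ``min_area_mm2`` are dropped as noise.
    Diameter is the major-axis length of the second-moment ellipse.
    """
    if not mpp > 0:
        raise ValueError("mpp must be positive")
    if perimeter_method not in ("crofton", "contour"):
        raise ValueError("perimeter_method must be 'crofton' or 'contour'")
    mask = np.asarray(mask, dtype=bool)
    mm_per_px = mpp / 1000.0
    px_area_mm2 = mm_per_px**2

    labels = skmeasure.label(mask, connectivity=2)
    lesions: list[Lesion] = []
    for rp in skmeasure.regionprops(labels):
        area_mm2 = rp.area * px_area_mm2
        if area_mm2 < min_area_mm2:
            continue
        if perimeter_method == "crofton":
            perim_px = rp.perimeter_crofton
        else:
            perim_px = _perimeter_contour(labels[rp.slice] == rp.label)
        lesions.append(
            Lesion(
                label=rp.label,
                area_mm2=float(area_mm2),
                perimeter_mm=float(perim_px * mm_per_px),
                diameter_mm=float(rp.axis_major_length * mm_per_px),
                eccentricity=float(rp.eccentricity),
                extent=float(rp.extent),
                solidity=float(rp.solidity),
                area_px=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    return LesionSet(lesions=lesions, mpp=mpp)


def _moment_aggregates(x: np.ndarray) -> dict[str, float]:
    """Seven-moment summary of a per-lesion value list; <3 samples set
    skewness/kurtosis to 0, empty lists produce all-zero defaults."""
    if x.size == 0:
        return {a: 0.0 for a in _AGGS}
    out = {
        "max": float(x.max()),
        "min": float(x.min()),
        "mean": float(x.mean()),
        "std": float(x.std()),
        "var": float(x.var()),
    }
    if x.size >= 3 and x.std() > 1e-9:
        out["skew"] = float(sstats.skew(x))
        out["kurt"] = float(sstats.kurtosis(x))
    else:
        out["skew"] = 0.0
        out["kurt"] = 0.0
    return out


def _distribution_stats(vals: np.ndarray, n_bins: int) -> dict[str, float]:
    """max/min/mean/sd/var/skew/kurt plus histogram entropy (bits) and energy."""
    if vals.size == 0:
        return {s: 0.0 for s in _DIST_STATS}
    out = {
        "max": float(vals.max()),
        "min": float(vals.min()),
        "mean": float(vals.mean()),
        "std": float(vals.std()),
        "var": float(vals.var()),
    }
    # tolerance absorbs the float dust a constant array leaves in np.std
    if vals.size >= 3 and vals.std() > 1e-9:
        out["skew"] = float(sstats.skew(vals))
        out["kurt"] = float(sstats.kurtosis(vals))
    else:
        out["skew"] = 0.0
        out["kurt"] = 0.0
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        hist, _ = np.histogram(vals, bins=n_bins, range=(lo, hi))
    else:
        hist = np.array([vals.size])
    p = hist[hist > 0] / vals.size
    out["entropy"] = float(-(p * np.log2(p)).sum())
    out["energy"] = float((p**2).sum())
    return out


def texture_features(
    heatmap: Heatmap,
    tissue: np.ndarray,
    glcm_levels: int = 32,
    angles: Sequence[float] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4),
) -> dict[str, float]:
    """Intensity, gradient and co-occurrence statistics of the heatmap.

    Intensity and gradient-magnitude statistics are taken over tissue pixels;
    co-occurrence statistics are computed on the full heatmap quantized to
    ``glcm_levels`` grey levels at distance 1, averaged over ``angles``.
    A degenerate (single grey level) heatmap has its correlation set to 0.
    """
    tissue = np.asarray(tissue, dtype=bool)
    if tissue.shape != heatmap.probs.shape:
        raise ValueError("tissue mask and heatmap dimensions differ")
    if not tissue.any():
        raise ValueError("tissue mask is empty")
    probs = heatmap.probs

    out: dict[str, float] = {}
    for k, v in _distribution_stats(probs[tissue], glcm_levels).items():
        out[f"intensity_{k}"] = v

    gy, gx = np.gradient(probs)
    gmag = np.hypot(gy, gx)
    for k, v in _distribution_stats(gmag[tissue], glcm_levels).items():
        out[f"gradient_{k}"] = v

    q = np.clip((probs * glcm_levels).astype(np.int64), 0, glcm_levels - 1).astype(np.uint8)
    glcm = skfeature.graycomatrix(
        q, distances=[1], angles=list(angles), levels=glcm_levels, symmetric=True, normed=True
    )
    for stat in _GLCM_STATS:
        out[f"glcm_{stat}"] = float(skfeature.graycoprops(glcm, stat).mean())
    if q.min() == q.max():  # single-symbol co-occurrence: correlation undefined
        out["glcm_correlation"] = 0.0
    return out


def marginal_features(heatmap: Heatmap, sigma: float = 1.0) -> tuple[int, float]:
    """Canny edge statistics of the probability raster.

    Returns ``(edge_pixel_count, mean Sobel gradient magnitude over edge
    pixels)``; a flat map returns ``(0, 0.0)`` by convention.
    """
    probs = heatmap.probs
    if probs.size == 0 or probs.max() == probs.min():
        return 0, 0.0
    edges = skfeature.canny(probs, sigma=sigma)
    n = int(edges.sum())
    if n == 0:
        return 0, 0.0
    gmag = skfilters.sobel(probs)
    return n, float(gmag[edges].mean())


def feature_vector(
    heatmap: Heatmap,
    tissue: np.ndarray | None = None,
    config: FeatureConfig | None = None,
) -> pd.Series:
    """Assemble the full named feature bank for one slide.

    ``tissue`` defaults to the whole raster. Slides with no lesions after
    binarization produce zero geometry aggregates (never NaN).
    """
    config = config or FeatureConfig()
    if tissue is None:
        tissue = np.ones_like(heatmap.probs, dtype=bool)

    mask = binarize(heatmap, config.threshold)
    lesions = extract_lesions(
        mask, heatmap.mpp, config.min_lesion_area_mm2, config.perimeter_method
    )

    values: dict[str, float] = {}
    for prop in _GEOM_PROPS:
        aggs = _moment_aggregates(lesions.values(prop))
        for agg, v in aggs.items():
            values[f"lesion_{prop}_{agg}"] = v

    values.update(texture_features(heatmap, tissue, config.glcm_levels))

    canny_nonzero, canny_mean = marginal_features(heatmap, config.canny_sigma)
    values["canny_nonzero"] = float(canny_nonzero)
    values["canny_mean"] = canny_mean
    values["region_count"] = float(len(lesions))
    values["lesion_pixel_count"] = float(int(lesions.values("area_px").sum()))

    vec = pd.Series([values[name] for name in FEATURE_NAMES], index=list(FEATURE_NAMES))
    vec.name = heatmap.slide_id
    return vec
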