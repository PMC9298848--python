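"""Synthetic frozen-section slide cohort with known ground truth.

Clinical whole-slide scans of thyroid frozen sections cannot be shipped with
the package, so every downstream stage is exercised on generated slides:
stained tissue blobs on a white scanner background, lesions drawn as
radial-harmonic perturbations of a disk (so area, diameter and boundary
irregularity — hence perimeter — are controlled and invertible), and pale
fibrotic-band streaks as the confounder that drives false positives on real
material.

Six subtypes are emulated. PTC (papillary thyroid carcinoma) and NG (nodular
goiter) are the common malignant/benign pair; TAL and TFCN are the
"intermediate" disputed nodules (round, mid-sized lesions); OtherTC and
OtherBTL are the low-incidence tails. PTC, OtherTC, TAL and TFCN count as
positive for the binary label, NG and OtherBTL as negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

__all__ = [
    "SUBTYPES",
    "POSITIVE_SUBTYPES",
    "TextureParams",
    "PhenotypeSpec",
    "SlideRecord",
    "CohortConfig",
    "PlacementError",
    "CohortConfigError",
    "DEFAULT_PHENOTYPES",
    "DEFAULT_MPP",
    "COHORT_MPP",
    "binary_label_for",
    "default_subtype_mix",
    "generate_slide",
    "generate_cohort",
    "slides_in_test1",
    "slides_in_test2",
]

SUBTYPES = ("PTC", "NG", "TAL", "TFCN", "OtherTC", "OtherBTL")
POSITIVE_SUBTYPES = frozenset({"PTC", "OtherTC", "TAL", "TFCN"})
RARE_SUBTYPES = frozenset({"TAL", "TFCN", "OtherTC", "OtherBTL"})
SPLITS = ("train", "val", "test1", "test2")

#: default µm per pixel at 5x-equivalent magnification (0.25 µm at 40x, ×8)
DEFAULT_MPP = 2.0
#: cohort-level default: emulates the same slides at a coarser pyramid level so
#: clinically sized lesions (units of mm) fit in ≤1024-px rasters
COHORT_MPP = 32.0

_BG_GRAY = 245.0
_TISSUE_RGB = (205.0, 155.0, 185.0)
_FIBROSIS_RGB = (150.0, 105.0, 135.0)


class PlacementError(ValueError):
    """Raised when requested lesions cannot be placed on a slide."""


class CohortConfigError(ValueError):
    """Raised for invalid cohort requests (counts, splits, subtypes)."""


@dataclass(frozen=True)
class TextureParams:
    """Stain rendering knobs: lesion stain intensity (mean/sd on the 0–255
    scale) and the expected number of fibrotic-band streaks per slide."""

    stain_mean: float = 110.0
    stain_sd: float = 8.0
    fibrosis_density: float = 0.5


@dataclass(frozen=True)
class PhenotypeSpec:
    """Morphology recipe for one subtype.

    ``boundary_irregularity`` is the summed radial-harmonic amplitude; 0 gives
    a circle (perimeter within 5% of the equal-area circle), larger values
    give the invasive, ragged edges typical of malignant lesions and inflate
    the perimeter the triage tree keys on.
    """

    subtype: str
    lesion_count_range: tuple[int, int]
    lesion_area_range: tuple[float, float]  # mm² per lesion
    boundary_irregularity: float = 0.0
    texture_params: TextureParams = field(default_factory=TextureParams)
    seed: int = 0

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise CohortConfigError(f"unknown subtype {self.subtype!r}")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise CohortConfigError("lesion_count_range must be ordered and non-negative")
        a_lo, a_hi = self.lesion_area_range
        if not (0 < a_lo <= a_hi):
            raise CohortConfigError("lesion_area_range must be positive and ordered")
        if self.boundary_irregularity < 0:
            raise CohortConfigError("boundary_irregularity must be >= 0")


#: subtype morphology defaults at cohort scale (areas in mm²): malignant
#: phenotypes carry large, irregular lesions; the intermediates (TAL/TFCN)
#: round mid-sized nodules; the benign subtypes no tumor but dense fibrosis.
DEFAULT_PHENOTYPES: dict[str, PhenotypeSpec] = {
    "PTC": PhenotypeSpec(
        "PTC", (1, 2), (60.0, 90.0), 0.35, TextureParams(fibrosis_density=0.4)
    ),
    "OtherTC": PhenotypeSpec(
        "OtherTC", (1, 2), (60.0, 90.0), 0.40, TextureParams(fibrosis_density=0.4)
    ),
    "TAL": PhenotypeSpec(
        "TAL", (2, 3), (7.0, 25.0), 0.05, TextureParams(fibrosis_density=0.8)
    ),
    "TFCN": PhenotypeSpec(
        "TFCN", (2, 3), (8.0, 25.0), 0.08, TextureParams(fibrosis_density=0.8)
    ),
    "NG": PhenotypeSpec("NG", (0, 0), (1.0, 2.0), 0.0, TextureParams(fibrosis_density=2.0)),
    "OtherBTL": PhenotypeSpec(
        "OtherBTL", (0, 0), (1.0, 2.0), 0.0, TextureParams(fibrosis_density=2.0)
    ),
}

#: case-series subtype prevalence (fractions of all slides) used to mimic a
#: real-world mix when only a total count is requested
SUBTYPE_PREVALENCE = {
    "PTC": 0.3901,
    "NG": 0.5029,
    "TAL": 0.0524,
    "TFCN": 0.0328,
    "OtherTC": 0.0036,
    "OtherBTL": 0.0182,
}


def binary_label_for(subtype: str) -> str:
    if subtype not in SUBTYPES:
        raise CohortConfigError(f"unknown subtype {subtype!r}")
    return "malignant" if subtype in POSITIVE_SUBTYPES else "benign"


@dataclass(frozen=True)
class SlideRecord:
    """One generated slide: RGB raster, physical scale, ground-truth lesion
    mask, subtype and derived binary label."""

    image: np.ndarray  # (H, W, 3) uint8
    mpp: float
    lesion_mask: np.ndarray  # (H, W) bool
    subtype: str
    binary_label: str
    slide_id: str

    def __post_init__(self):
        if self.image.shape[:2] != self.lesion_mask.shape:
            raise ValueError("image and lesion_mask dimensions differ")
        if self.binary_label != binary_label_for(self.subtype):
            raise ValueError(
                f"binary_label {self.binary_label!r} inconsistent with subtype {self.subtype!r}"
            )


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` by ``weights`` (exact sum)."""
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    w = np.asarray(weights, dtype=float)
    quota = total * w / w.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def default_subtype_mix(n_slides: int) -> dict[str, int]:
    """Scale the case-series subtype prevalence to ``n_slides`` slides."""
    names = list(SUBTYPE_PREVALENCE)
    counts = _largest_remainder(n_slides, np.array([SUBTYPE_PREVALENCE[s] for s in names]))
    return dict(zip(names, (int(c) for c in counts)))


def _lesion_polygon(
    rng: np.random.Generator, target_area_px: float, irregularity: float
) -> np.ndarray:
    """Closed boundary r(θ) = r0·(1 + Σ a_k cos(kθ + φ_k)), scaled so the
    polygon's shoelace area equals ``target_area_px`` exactly."""
    theta = np.linspace(0.0, 2 * np.pi, 256, endpoint=False)
    r = np.ones_like(theta)
    if irregularity > 0:
        harmonics = rng.integers(3, 9, size=3)
        amps = rng.dirichlet(np.ones(3)) * irregularity
        phases = rng.uniform(0, 2 * np.pi, size=3)
        for k, a, phi in zip(harmonics, amps, phases):
            r += a * np.cos(k * theta + phi)
    r = np.clip(r, 0.1, None)
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    scale = math.sqrt(target_area_px / area)
    return np.stack([y * scale, x * scale], axis=1)  # (row, col) offsets


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def generate_slide(
    spec: PhenotypeSpec,
    dims: tuple[int, int],
    seed: int,
    mpp: float = DEFAULT_MPP,
    slide_id: str | None = None,
) -> SlideRecord:
    """Render one slide with ground truth.

    Each lesion's rasterized pixel area, converted through ``mpp``, lies
    within 10% of its drawn target area. Deterministic for a fixed seed.
    An unlucky tissue/lesion layout is redrawn (deterministically) a few
    times; :class:`PlacementError` is raised only when the requested lesions
    genuinely cannot be placed on a slide of the given size.
    """
    h, w = int(dims[0]), int(dims[1])
    if h < 512 or w < 512:
        raise ValueError("slide dimensions must be at least 512x512")
    if not mpp > 0:
        raise ValueError("mpp must be positive")
    last_err: PlacementError | None = None
    for relayout in range(5):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), relayout)))
        try:
            return _generate_once(spec, (h, w), rng, mpp, slide_id, seed)
        except PlacementError as err:
            last_err = err
    raise last_err


def _generate_once(
    spec: PhenotypeSpec,
    dims: tuple[int, int],
    rng: np.random.Generator,
    mpp: float,
    slide_id: str | None,
    seed: int,
) -> SlideRecord:
    h, w = dims
    px_area_mm2 = (mpp / 1000.0) ** 2

    n_lesions = int(rng.integers(spec.lesion_count_range[0], spec.lesion_count_range[1] + 1))
    # multifocal slides carry one dominant lesion drawn from the area range
    # plus smaller satellite foci, as in multifocal carcinoma
    targets_mm2 = np.empty(n_lesions)
    if n_lesions:
        targets_mm2[0] = rng.uniform(*spec.lesion_area_range)
        targets_mm2[1:] = targets_mm2[0] * rng.uniform(0.25, 0.5, size=n_lesions - 1)
    polys = [
        _lesion_polygon(rng, t / px_area_mm2, spec.boundary_irregularity) for t in targets_mm2
    ]
    radii = [float(np.hypot(p[:, 0], p[:, 1]).max()) for p in polys] or [0.0]

    # main tissue blob: a rotated ellipse sized to host all requested lesions
    dim = min(h, w)
    need = 1.25 * max(radii) * math.sqrt(max(1, n_lesions))
    a = max(rng.uniform(0.30, 0.40) * dim, need)
    b = max(rng.uniform(0.30, 0.40) * dim, need)
    if max(a, b) > 0.46 * dim:
        if need > 0.46 * dim:
            raise PlacementError(
                f"slide of {h}x{w} px at {mpp} µm/px too small for a lesion of "
                f"max radius {max(radii):.0f} px"
            )
        a, b = min(a, 0.46 * dim), min(b, 0.46 * dim)
    center = (
        h / 2 + rng.uniform(-0.03, 0.03) * h,
        w / 2 + rng.uniform(-0.03, 0.03) * w,
    )
    angle = rng.uniform(0, np.pi)
    tissue = _ellipse_mask((h, w), center, (a, b), angle)
    for _ in range(int(rng.integers(1, 3))):  # satellite fragments
        off = rng.uniform(-0.35, 0.35, size=2) * (a, b)
        tissue |= _ellipse_mask(
            (h, w),
            (center[0] + off[0], center[1] + off[1]),
            (a * rng.uniform(0.25, 0.45), b * rng.uniform(0.25, 0.45)),
            rng.uniform(0, np.pi),
        )

    # place lesions inside the main ellipse: big lesions first, one angular
    # sector per lesion, a cheap center-distance prefilter, then pixel-level
    # containment/overlap checks on a slightly inflated outline so separate
    # lesions never touch (adjacent components would merge under 8-connectivity)
    lesion_mask = np.zeros((h, w), dtype=bool)
    ca, sa = math.cos(angle), math.sin(angle)
    n_placed = len(polys)
    order = sorted(range(n_placed), key=lambda i: -radii[i])
    sector_offset = rng.uniform(0, 2 * np.pi)
    placed_centers: list[tuple[float, float, float]] = []
    for slot, i in enumerate(order):
        poly, r_les = polys[i], radii[i]
        inflated = poly * (1.0 + 4.0 / max(r_les, 1.0))
        placed = False
        for _ in range(400):
            rho_max = max(0.15, 1.0 - 0.8 * r_les / min(a, b))
            rho = math.sqrt(rng.uniform()) * rho_max
            if n_placed > 1:
                rho = max(rho, 0.25 * rho_max)
                phi = sector_offset + 2 * np.pi * (slot + rng.uniform(0.1, 0.9)) / n_placed
            else:
                phi = rng.uniform(0, 2 * np.pi)
            u, v = rho * a * math.cos(phi), rho * b * math.sin(phi)
            cr = center[0] + u * ca - v * sa
            cc_ = center[1] + u * sa + v * ca
            if any(
                math.hypot(cr - pr, cc_ - pc) < 0.7 * (r_les + pr_rad)
                for pr, pc, pr_rad in placed_centers
            ):
                continue
            rows = inflated[:, 0] + cr
            cols = inflated[:, 1] + cc_
            if rows.min() < 1 or cols.min() < 1 or rows.max() >= h - 1 or cols.max() >= w - 1:
                continue
            rr, cc = draw_polygon(rows, cols, shape=(h, w))
            if (~tissue[rr, cc]).any() or lesion_mask[rr, cc].any():
                continue
            rr, cc = draw_polygon(poly[:, 0] + cr, poly[:, 1] + cc_, shape=(h, w))
            lesion_mask[rr, cc] = True
            placed_centers.append((cr, cc_, r_les))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a lesion of {r_les:.0f} px radius on a "
                f"{h}x{w} slide after 400 attempts"
            )

    # fibrotic-band streaks: thin elongated rectangles inside tissue
    fibrosis = np.zeros((h, w), dtype=bool)
    for _ in range(rng.poisson(spec.texture_params.fibrosis_density)):
        r0 = center[0] + rng.uniform(-0.6, 0.6) * a
        c0 = center[1] + rng.uniform(-0.6, 0.6) * b
        band_angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.15, 0.40) * dim
        half_w = rng.uniform(3, 9)
        dr, dc = math.sin(band_angle), math.cos(band_angle)
        corners_r = [
            r0 - dr * length / 2 - dc * half_w, r0 - dr * length / 2 + dc * half_w,
            r0 + dr * length / 2 + dc * half_w, r0 + dr * length / 2 - dc * half_w,
        ]
        corners_c = [
            c0 - dc * length / 2 + dr * half_w, c0 - dc * length / 2 - dr * half_w,
            c0 + dc * length / 2 - dr * half_w, c0 + dc * length / 2 + dr * half_w,
        ]
        rr, cc = draw_polygon(corners_r, corners_c, shape=(h, w))
        fibrosis[rr, cc] = True
    fibrosis &= tissue & ~lesion_mask

    # render: white background, pink tissue, pale-dense fibrosis, dark lesions
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = _BG_GRAY
    img += rng.normal(0.0, 3.0, size=img.shape)
    tp = spec.texture_params
    lesion_rgb = (0.85 * tp.stain_mean, 0.60 * tp.stain_mean, 1.00 * tp.stain_mean)
    for region, rgb, sd in (
        (tissue & ~lesion_mask & ~fibrosis, _TISSUE_RGB, 6.0),
        (fibrosis, _FIBROSIS_RGB, 6.0),
        (lesion_mask, lesion_rgb, tp.stain_sd),
    ):
        n = int(region.sum())
        if n:
            img[region] = np.asarray(rgb) + rng.normal(0.0, sd, size=(n, 3))
    image = np.clip(img, 0, 255).astype(np.uint8)

    return SlideRecord(
        image=image,
        mpp=mpp,
        lesion_mask=lesion_mask,
        subtype=spec.subtype,
        binary_label=binary_label_for(spec.subtype),
        slide_id=slide_id or f"{spec.subtype}_{seed}",
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort request.

    ``counts`` maps subtype to either a total (split automatically: common
    subtypes by ``split_fractions`` into train/val/test1, rare subtypes
    entirely into test2) or an explicit per-split mapping. Rare subtypes in
    train/val are rejected: the segmenter and slide classifier are trained on
    the common pair only. ``split == "test1"`` rows belong to both test sets;
    ``"test2"`` rows are test2-only.
    """

    counts: Mapping[str, int | Mapping[str, int]]
    dims: tuple[int, int] = (1024, 1024)
    mpp: float = COHORT_MPP
    split_fractions: tuple[float, float, float] = (0.4, 0.1, 0.5)  # train, val, test1
    phenotypes: Mapping[str, PhenotypeSpec] | None = None


def _split_rows(config: CohortConfig) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    for subtype, req in config.counts.items():
        if subtype not in SUBTYPES:
            raise CohortConfigError(f"unknown subtype {subtype!r}")
        if isinstance(req, Mapping):
            per_split = {s: int(req.get(s, 0)) for s in SPLITS}
            if any(v < 0 for v in per_split.values()):
                raise CohortConfigError("per-split counts must be >= 0")
            if subtype in RARE_SUBTYPES and (per_split["train"] or per_split["val"]):
                raise CohortConfigError(
                    f"{subtype} requested in train/val: training uses PTC and NG only"
                )
            for split in SPLITS:
                rows += [(subtype, split)] * per_split[split]
        else:
            total = int(req)
            if total < 0:
                raise CohortConfigError("subtype counts must be >= 0")
            if subtype in RARE_SUBTYPES:
                rows += [(subtype, "test2")] * total
            else:
                parts = _largest_remainder(total, np.array(config.split_fractions))
                for split, n in zip(("train", "val", "test1"), parts):
                    rows += [(subtype, split)] * int(n)
    return rows


def generate_cohort(
    config: CohortConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[SlideRecord]]:
    """Generate a full cohort; returns (manifest, slides).

    The manifest has columns ``slide_id, subtype, split, binary_label``.
    One global seed fans out to per-slide seeds through a fixed counter
    scheme (``SeedSequence((seed, index))``), so cohorts are reproducible
    slide-by-slide. When ``out_dir`` is given, slides and masks are written
    as PNG and the manifest as ``manifest.csv``.
    """
    phenotypes = dict(DEFAULT_PHENOTYPES)
    if config.phenotypes:
        phenotypes.update(config.phenotypes)
    rows = _split_rows(config)

    records: list[SlideRecord] = []
    manifest_rows = []
    for idx, (subtype, split) in enumerate(rows):
        child_seed = int(np.random.SeedSequence((seed, idx)).generate_state(1)[0] % 2**31)
        slide_id = f"s{idx:04d}_{subtype}"
        rec = generate_slide(
            phenotypes[subtype], config.dims, child_seed, mpp=config.mpp, slide_id=slide_id
        )
        records.append(rec)
        manifest_rows.append(
            {
                "slide_id": slide_id,
                "subtype": subtype,
                "split": split,
                "binary_label": rec.binary_label,
            }
        )
    manifest = pd.DataFrame(
        manifest_rows, columns=["slide_id", "subtype", "split", "binary_label"]
    )

    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        (out / "slides").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for rec in records:
            iio.imwrite(out / "slides" / f"{rec.slide_id}.png", rec.image)
            iio.imwrite(
                out / "masks" / f"{rec.slide_id}.png",
                (rec.lesion_mask * np.uint8(255)),
            )
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest, records


def slides_in_test1(manifest: pd.DataFrame) -> list[str]:
    """Slides of the common-subtype test series."""
    return manifest.loc[manifest["split"] == "test1", "slide_id"].tolist()


def slides_in_test2(manifest: pd.DataFrame) -> list[str]:
    """Slides of the real-world test series (test1 plus the rare subtypes)."""
    return manifest.loc[manifest["split"].isin(["test1", "test2"]), "slide_id"].tolist()
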