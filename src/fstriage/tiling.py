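"""Tissue masking, training-patch sampling, inference tiling and stitching.

Inference follows the tile/core scheme: the slide is conceptually padded by
half a core (128 px) per border with white background, covered by 512×512
tiles at stride 256, and only each tile's central 256×256 core is kept when
the heatmap is stitched — the 128-px margins are abandoned to suppress edge
artifacts. Cores partition the original raster exactly.

Coordinates are 0-based, (row, col), half-open intervals, origin top-left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu

from .features import Heatmap
from .synthetic import SlideRecord

__all__ = [
    "TileGrid",
    "PatchSample",
    "tissue_mask",
    "build_tile_grid",
    "extract_tiles",
    "assemble_heatmap",
    "sample_training_patches",
]

TILE_SIZE = 512
STRIDE = 256
CORE_SIZE = 256
MARGIN = (TILE_SIZE - CORE_SIZE) // 2  # 128 px abandoned per tile edge


@dataclass(frozen=True)
class TileGrid:
    """Tile/core layout for one slide.

    ``tile_origins`` are in the padded frame (slide shifted by ``MARGIN``),
    ``core_origins`` in the original frame; ``core_shapes`` give each core's
    actual extent (edge cores may be cut by the slide border). Cores are
    pairwise disjoint and their union is exactly the unpadded raster.
    """

    slide_shape: tuple[int, int]
    tile_size: int = TILE_SIZE
    stride: int = STRIDE
    core_size: int = CORE_SIZE
    pad: tuple[int, int, int, int] = (MARGIN, MARGIN, MARGIN, MARGIN)  # top, bottom, left, right
    tile_origins: tuple[tuple[int, int], ...] = field(default=())
    core_origins: tuple[tuple[int, int], ...] = field(default=())
    core_shapes: tuple[tuple[int, int], ...] = field(default=())

    def __len__(self) -> int:
        return len(self.tile_origins)

    @property
    def padded_shape(self) -> tuple[int, int]:
        h, w = self.slide_shape
        top, bottom, left, right = self.pad
        return (h + top + bottom, w + left + right)


def tissue_mask(image: np.ndarray) -> np.ndarray:
    """Otsu foreground mask: pixels darker than the grayscale Otsu threshold.

    Stained tissue is dark on a white scanner background, so tissue is the
    sub-threshold class. A constant image yields an all-background mask.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        gray = rgb2gray(image)
    else:
        gray = image.astype(np.float64)
        if image.dtype == np.uint8:
            gray = gray / 255.0
    if gray.max() == gray.min():
        return np.zeros(gray.shape, dtype=bool)
    t = threshold_otsu(gray)
    return gray < t


def build_tile_grid(slide_dims: tuple[int, int]) -> TileGrid:
    """Lay out 512-px tiles at stride 256 whose 256-px cores tile the slide.

    The slide is conceptually padded by 128 px per border (plus bottom/right
    slack up to the next core multiple); abandoning each tile's 128-px margin
    leaves cores exactly partitioning the original raster. Origins row-major.
    """
    h, w = int(slide_dims[0]), int(slide_dims[1])
    if h < 1 or w < 1:
        raise ValueError("slide dimensions must be at least 1x1")
    n_rows = -(-h // CORE_SIZE)
    n_cols = -(-w // CORE_SIZE)
    pad = (MARGIN, n_rows * CORE_SIZE - h + MARGIN, MARGIN, n_cols * CORE_SIZE - w + MARGIN)

    tile_origins = []
    core_origins = []
    core_shapes = []
    for i in range(n_rows):
        for j in range(n_cols):
            tile_origins.append((i * STRIDE, j * STRIDE))
            r0, c0 = i * CORE_SIZE, j * CORE_SIZE
            core_origins.append((r0, c0))
            core_shapes.append((min(CORE_SIZE, h - r0), min(CORE_SIZE, w - c0)))
    return TileGrid(
        slide_shape=(h, w),
        pad=pad,
        tile_origins=tuple(tile_origins),
        core_origins=tuple(core_origins),
        core_shapes=tuple(core_shapes),
    )


def _pad_raster(raster: np.ndarray, grid: TileGrid, fill) -> np.ndarray:
    top, bottom, left, right = grid.pad
    pad_width = [(top, bottom), (left, right)] + [(0, 0)] * (raster.ndim - 2)
    return np.pad(raster, pad_width, mode="constant", constant_values=fill)


def extract_tiles(raster: np.ndarray, grid: TileGrid, fill=255) -> list[np.ndarray]:
    """Cut the grid's 512×512 tiles out of a slide raster (image or prob map),
    padding borders with ``fill`` (white background for RGB images)."""
    if raster.shape[:2] != grid.slide_shape:
        raise ValueError(
            f"raster shape {raster.shape[:2]} does not match grid slide shape {grid.slide_shape}"
        )
    padded = _pad_raster(raster, grid, fill)
    ts = grid.tile_size
    return [padded[r : r + ts, c : c + ts] for r, c in grid.tile_origins]


def assemble_heatmap(
    grid: TileGrid,
    tile_probs: list[np.ndarray],
    mpp: float,
    slide_id: str = "",
) -> Heatmap:
    """Stitch per-tile probability rasters into the slide heatmap.

    Each output pixel is taken from the unique tile whose core contains it;
    tile margins are discarded. One 512×512 probability raster per grid tile
    is required.
    """
    if len(tile_probs) != len(grid):
        present = len(tile_probs)
        missing = [o for k, o in enumerate(grid.tile_origins) if k >= present]
        raise ValueError(f"missing probability rasters for tile origins {missing}")
    out = np.empty(grid.slide_shape, dtype=np.float64)
    ts, m = grid.tile_size, MARGIN
    for probs, origin, (r0, c0), (ch, cw) in zip(
        tile_probs, grid.tile_origins, grid.core_origins, grid.core_shapes
    ):
        probs = np.asarray(probs, dtype=np.float64)
        if probs.shape != (ts, ts):
            raise ValueError(
                f"tile at origin {origin}: expected {ts}x{ts} probabilities, got {probs.shape}"
            )
        out[r0 : r0 + ch, c0 : c0 + cw] = probs[m : m + ch, m : m + cw]
    return Heatmap(probs=np.clip(out, 0.0, 1.0), mpp=mpp, slide_id=slide_id)


@dataclass(frozen=True)
class PatchSample:
    """One training patch with its pixel-level supervision crop."""

    image: np.ndarray  # (patch, patch, 3) uint8
    mask: np.ndarray  # (patch, patch) bool lesion crop
    label: str  # "malignant" | "benign" (center-pixel rule)
    slide_id: str
    origin: tuple[int, int]  # top-left corner, slide frame


def sample_training_patches(
    slide: SlideRecord,
    n_total: int,
    ratio: int,
    seed: int,
    patch_size: int = 256,
    min_tissue_frac: float = 0.25,
) -> list[PatchSample]:
    """Sample class-exact patches from one slide.

    Exactly ``floor(n_total / (1 + ratio))`` malignant patches and the
    remainder benign (``ratio`` = benign per malignant). A patch is malignant
    iff its center pixel lies inside the lesion mask; every center lies in
    tissue and the patch must contain at least ``min_tissue_frac`` tissue.
    If a class has fewer eligible centers than requested, sampling falls back
    to replacement with a warning. Deterministic for a fixed seed.
    """
    if n_total < 0 or ratio < 0:
        raise ValueError("n_total and ratio must be non-negative")
    if n_total == 0:
        return []
    n_mal = n_total // (1 + ratio)
    n_ben = n_total - n_mal

    img = slide.image
    h, w = img.shape[:2]
    if patch_size > min(h, w):
        raise ValueError(f"patch size {patch_size} exceeds slide dims {(h, w)}")
    tissue = tissue_mask(img)
    if not tissue.any():
        raise ValueError("slide has no tissue")
    lesion = slide.lesion_mask.astype(bool)
    if n_mal > 0 and not lesion.any():
        raise ValueError("malignant patches requested but lesion mask is empty")

    half = patch_size // 2
    valid = np.zeros_like(tissue)
    valid[half : h - (patch_size - half) + 1, half : w - (patch_size - half) + 1] = True

    rng = np.random.default_rng(seed)
    frac_kernel_area = patch_size * patch_size

    def _draw(class_mask: np.ndarray, n: int) -> list[tuple[int, int]]:
        centers = np.flatnonzero(class_mask & tissue & valid)
        if centers.size == 0:
            raise ValueError("no eligible patch centers for requested class")
        order = rng.permutation(centers)
        picked: list[tuple[int, int]] = []
        for idx in order:
            r, c = divmod(int(idx), w)
            r0, c0 = r - half, c - half
            if tissue[r0 : r0 + patch_size, c0 : c0 + patch_size].sum() >= (
                min_tissue_frac * frac_kernel_area
            ):
                picked.append((r0, c0))
                if len(picked) == n:
                    return picked
        if not picked:
            raise ValueError("no patch satisfies the minimum tissue fraction")
        warnings.warn(
            f"slide {slide.slide_id}: only {len(picked)} distinct positions for {n} "
            "requested patches; sampling with replacement",
            stacklevel=2,
        )
        extra = rng.integers(0, len(picked), size=n - len(picked))
        return picked + [picked[k] for k in extra]

    samples: list[PatchSample] = []
    for class_mask, n, label in ((lesion, n_mal, "malignant"), (~lesion, n_ben, "benign")):
        if n == 0:
            continue
        for r0, c0 in _draw(class_mask, n):
            samples.append(
                PatchSample(
                    image=img[r0 : r0 + patch_size, c0 : c0 + patch_size].copy(),
                    mask=lesion[r0 : r0 + patch_size, c0 : c0 + patch_size].copy(),
                    label=label,
                    slide_id=slide.slide_id,
                    origin=(r0, c0),
                )
            )
    return samples
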