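"""Configuration, annotation I/O and raster read/write helpers.

Annotations use the ASAP XML dialect (nested ``Annotation`` elements with a
``Coordinates`` list of ``X``/``Y`` attributes, X = column, Y = row), the
format the lesion outlines were drawn in. Polygons can be rasterized to
masks and written back losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from lxml import etree
from pydantic import BaseModel, ConfigDict, Field
from skimage.draw import polygon as draw_polygon

__all__ = [
    "Polygon",
    "read_asap_annotations",
    "write_asap_annotations",
    "rasterize_polygons",
    "RunConfig",
    "config_hash",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class Polygon:
    """One annotation outline: vertices as an (n, 2) float array in (x, y)
    scanner order, with its annotation name and group label."""

    name: str
    group: str
    vertices: np.ndarray


def read_asap_annotations(path: str | Path, scale: float = 1.0) -> list[Polygon]:
    """Parse an ASAP annotation file into polygons.

    ``scale`` multiplies the stored coordinates, mapping level-0 scanner
    coordinates to the working magnification. Malformed XML or a polygon
    with fewer than 3 vertices raises with element context.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed ASAP XML in {path}: {exc}") from exc
    polygons: list[Polygon] = []
    for ann in tree.iter("Annotation"):
        name = ann.get("Name", "")
        group = ann.get("PartOfGroup", "")
        coords = ann.find("Coordinates")
        if coords is None:
            raise ValueError(f"annotation {name!r} in {path} has no Coordinates element")
        pts = sorted(
            ((int(c.get("Order", i)), float(c.get("X")), float(c.get("Y")))
             for i, c in enumerate(coords.iter("Coordinate"))),
        )
        verts = np.array([[x, y] for _, x, y in pts], dtype=np.float64) * scale
        if verts.shape[0] < 3:
            raise ValueError(
                f"annotation {name!r} in {path} is not a closed polygon "
                f"({verts.shape[0]} vertices)"
            )
        polygons.append(Polygon(name=name, group=group, vertices=verts))
    return polygons


def write_asap_annotations(path: str | Path, polygons: Sequence[Polygon]):
    root = etree.Element("ASAP_Annotations")
    anns = etree.SubElement(root, "Annotations")
    groups = sorted({p.group for p in polygons if p.group})
    for p in polygons:
        ann = etree.SubElement(
            anns,
            "Annotation",
            Name=p.name,
            Type="Polygon",
            PartOfGroup=p.group or "None",
            Color="#F4FA58",
        )
        coords = etree.SubElement(ann, "Coordinates")
        for i, (x, y) in enumerate(np.asarray(p.vertices, dtype=float)):
            etree.SubElement(
                coords, "Coordinate", Order=str(i), X=repr(float(x)), Y=repr(float(y))
            )
    grp_el = etree.SubElement(root, "AnnotationGroups")
    for g in groups:
        etree.SubElement(grp_el, "Group", Name=g, PartOfGroup="None", Color="#64FE2E")
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


def rasterize_polygons(polygons: Sequence[Polygon], shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of all polygons; vertices are (x, y) = (col, row)."""
    mask = np.zeros(shape, dtype=bool)
    for p in polygons:
        rr, cc = draw_polygon(p.vertices[:, 1], p.vertices[:, 0], shape=shape)
        mask[rr, cc] = True
    return mask


def mask_to_polygons(mask: np.ndarray, group: str = "lesion") -> list[Polygon]:
    """Trace a binary mask's component outlines into annotation polygons."""
    from skimage.measure import find_contours

    polys = []
    for i, contour in enumerate(find_contours(np.asarray(mask, dtype=float), 0.5)):
        if contour.shape[0] < 3:
            continue
        verts = np.stack([contour[:, 1], contour[:, 0]], axis=1)  # (x, y)
        polys.append(Polygon(name=f"{group}_{i}", group=group, vertices=verts))
    return polys


# ------------------------------------------------------------- run config ---


class SamplingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patches_per_slide: int = 40
    benign_per_malignant: int = 3  # 1:3 malignant:benign sampling ratio
    patch_size: int = 256
    min_tissue_frac: float = 0.25


class SegmenterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    base_channels: int = 8
    depth: int = 4
    batch_size: int = 32
    initial_lr: float = 0.01
    lr_decay_rate: float = 0.94
    lr_decay_steps: int = 1000
    max_epochs: int = 20
    patience: int = 5


class ForestConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_estimators: int = 500
    max_depth: int | None = None
    top_k: int = 30
    importance: str = "impurity"


class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    prob_cut: float = 0.5
    area_cut: float = 300.0
    diameter_cut: float = 7.0
    perimeter_cut: float = 35.0


class OracleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    noise_sd: float = 0.1
    flip_rate: float = 0.05


class RunConfig(BaseModel):
    """Full pipeline configuration; round-trips losslessly through JSON and
    rejects unknown keys."""

    model_config = ConfigDict(extra="forbid")

    mpp: float = 32.0
    slide_dims: tuple[int, int] = (1024, 1024)
    tile_size: int = 512
    stride: int = 256
    core_size: int = 256
    binarize_threshold: float = 0.5
    min_lesion_area_mm2: float = 0.01
    sampling: SamplingConfig = Field(default_factory=SamplingConfig)
    segmenter: SegmenterConfig = Field(default_factory=SegmenterConfig)
    forest: ForestConfig = Field(default_factory=ForestConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    oracle: OracleConfig = Field(default_factory=OracleConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self, path: str | Path):
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())


def config_hash(config: RunConfig) -> str:
    """Stable digest of the configuration, logged with every stage."""
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# ------------------------------------------------------------ raster I/O ----


def write_image(path: str | Path, image: np.ndarray):
    """PNG for small rasters, tiled TIFF otherwise (by file suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image, tile=(256, 256))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def write_mask(path: str | Path, mask: np.ndarray):
    write_image(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 127
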