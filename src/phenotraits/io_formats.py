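"""Image, label-map and polygon-annotation I/O, plus trait-table writers.

Conventions used throughout the package:

* images are ``(H, W, 3)`` uint8 arrays in (R, G, B) channel order;
* instance label maps are ``(H, W)`` non-negative integer arrays where 0 is
  background and labels form the contiguous set ``{0..N}``;
* image coordinates are row-major with the origin at the top-left corner,
  ``x`` = column, ``y`` = row, 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from PIL import Image, UnidentifiedImageError

__all__ = [
    "FormatError",
    "PolygonAnnotation",
    "TraitRecord",
    "read_image",
    "read_label_map",
    "relabel_contiguous",
    "load_labelme",
    "rasterize_polygons",
    "write_trait_table",
]


class FormatError(ValueError):
    """Raised when an input file cannot be decoded in the expected format."""


@dataclass
class PolygonAnnotation:
    """Polygon instance annotation in the LabelMe dialect.

    ``shapes`` is an ordered list of ``(label, points)`` pairs where ``points``
    is an ``(n, 2)`` float array of ``(x, y)`` vertices in image coordinates.
    """

    shapes: list[tuple[str, np.ndarray]]
    image_height: int
    image_width: int


@dataclass
class TraitRecord:
    """One image's trait vector: an ordered name -> value mapping.

    ``traits`` holds exactly the 64-trait catalog for ``organ_class`` when
    produced by the measurement pipeline; undefined traits are NaN and are
    written as empty cells.
    """

    image_id: str
    organ_class: str
    traits: dict[str, float] = field(default_factory=dict)


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG image as an ``(H, W, 3)`` uint8 RGB array.

    16-bit inputs are rescaled to 8-bit; grayscale inputs are replicated to
    three channels with a warning.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            img.load()
            mode = img.mode
            if mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(img, dtype=np.float64)
                arr = np.clip(np.round(arr / 257.0), 0, 255).astype(np.uint8)
                warnings.warn(f"{path}: 16-bit image rescaled to 8-bit")
            elif mode == "L":
                arr = np.asarray(img, dtype=np.uint8)
            else:
                arr = np.asarray(img.convert("RGB"), dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot decode image file {path}: {exc}") from exc
    if arr.ndim == 2:
        warnings.warn(f"{path}: grayscale input replicated to 3 channels")
        arr = np.stack([arr] * 3, axis=-1)
    return arr


def relabel_contiguous(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel a label map to the contiguous set {0..N}.

    Positive labels are renumbered 1..N in order of first appearance in a
    raster scan; 0 stays background. Returns ``(relabeled, N)``. The pixel-set
    partition is preserved (only names change).
    """
    labels = np.asarray(labels)
    flat = labels.ravel()
    # order of first appearance under a raster scan
    uniq, first = np.unique(flat, return_index=True)
    pos = uniq[uniq > 0]
    order = np.argsort(first[uniq > 0], kind="stable")
    mapping = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    for new, old in enumerate(pos[order], start=1):
        mapping[old] = new
    out = mapping[labels] if labels.size else labels.astype(np.int32)
    return out, int(len(pos))


def read_label_map(path) -> np.ndarray:
    """Read a single-channel integer label map and relabel to {0..N}.

    Palette-mode PNGs are read as their raw indices. A genuine 3-channel
    image is rejected with instructions to convert it.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            img.load()
            if img.mode == "P":
                arr = np.asarray(img, dtype=np.int32)
            elif img.mode in ("L", "I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(img, dtype=np.int32)
            else:
                raise FormatError(
                    f"{path}: label maps must be single-channel integer images; "
                    f"got mode {img.mode!r} — convert to a paletted or grayscale "
                    "PNG with one integer label per pixel"
                )
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot decode label map {path}: {exc}") from exc
    out, _ = relabel_contiguous(arr)
    return out


def load_labelme(path) -> PolygonAnnotation:
    """Load a LabelMe-dialect JSON annotation file."""
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
        shapes = [
            (s.get("label", ""), np.asarray(s["points"], dtype=float))
            for s in doc["shapes"]
        ]
        return PolygonAnnotation(
            shapes=shapes,
            image_height=int(doc["imageHeight"]),
            image_width=int(doc["imageWidth"]),
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse LabelMe JSON {path}: {exc}") from exc


def rasterize_polygons(ann: PolygonAnnotation) -> np.ndarray:
    """Rasterize polygon shapes to an instance label map.

    A pixel belongs to a polygon iff its center lies inside under the even-odd
    rule; pixel centers exactly on the boundary count as inside. Shapes are
    rasterized in file order, with later shapes overwriting earlier ones on
    overlap. Polygons with fewer than 3 vertices are skipped with a warning.
    """
    h, w = ann.image_height, ann.image_width
    if h < 1 or w < 1:
        raise ValueError("annotation frame must be at least 1x1")
    out = np.zeros((h, w), dtype=np.int32)
    label = 0
    for name, pts in ann.shapes:
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or len(pts) < 3:
            warnings.warn(f"shape {name!r}: fewer than 3 vertices, skipped")
            continue
        label += 1
        poly = shapely.Polygon(pts)
        # invalid (self-intersecting) rings: fall back to even-odd scan below
        x0 = max(int(np.floor(pts[:, 0].min())), 0)
        x1 = min(int(np.ceil(pts[:, 0].max())), w - 1)
        y0 = max(int(np.floor(pts[:, 1].min())), 0)
        y1 = min(int(np.ceil(pts[:, 1].max())), h - 1)
        if x1 < x0 or y1 < y0:
            continue
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        if poly.is_valid:
            inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
        else:
            inside = _even_odd_inside(pts, xs.ravel(), ys.ravel())
        inside = inside.reshape(xs.shape)
        out[y0 : y1 + 1, x0 : x1 + 1][inside] = label
    out, _ = relabel_contiguous(out)
    return out


def _even_odd_inside(pts: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Even-odd ray casting with boundary points counted inside."""
    n = len(pts)
    inside = np.zeros(len(xs), dtype=bool)
    on_edge = np.zeros(len(xs), dtype=bool)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        crosses = ((y1 > ys) != (y2 > ys)) & (
            xs < (x2 - x1) * (ys - y1) / (y2 - y1 + 1e-300) + x1
        )
        inside ^= crosses
        # point-on-segment test
        d = np.abs((x2 - x1) * (ys - y1) - (y2 - y1) * (xs - x1))
        seg2 = (x2 - x1) ** 2 + (y2 - y1) ** 2
        t = ((xs - x1) * (x2 - x1) + (ys - y1) * (y2 - y1)) / (seg2 + 1e-300)
        on_edge |= (d <= 1e-9 * max(1.0, np.sqrt(seg2))) & (t >= 0) & (t <= 1)
    return inside | on_edge


def write_trait_table(records: list[TraitRecord], path, format: str = "csv") -> None:
    """Write trait records as a table with one row per image.

    All records must share one organ class (one column set). The column order
    is the catalog order of the records' trait dicts, prefixed by ``image_id``.
    ``format`` is ``"csv"`` (canonical) or ``"xlsx"``.
    """
    if format not in ("csv", "xlsx"):
        raise ValueError(f"unsupported trait-table format: {format!r}")
    classes = {r.organ_class for r in records}
    if len(classes) > 1:
        raise ValueError(f"mixed organ classes in one table: {sorted(classes)}")
    if records:
        columns = list(records[0].traits)
        rows = [{"image_id": r.image_id, **r.traits} for r in records]
        df = pd.DataFrame(rows, columns=["image_id"] + columns)
    else:
        df = pd.DataFrame(columns=["image_id"])
    if format == "csv":
        df.to_csv(path, index=False)
    else:
        df.to_excel(path, index=False, engine="openpyxl")
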