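"""Per-instance geometry and the 35 plant-level morphological traits.

Geometry conventions
--------------------
* **Area** is the pixel count of an instance's support.
* **Perimeter** is the length of the closed Moore-neighbor boundary trace
  through boundary *pixel centers*: axis steps contribute 1, diagonal steps
  sqrt(2). An n x n square therefore has perimeter 4(n-1); a single pixel has
  the degenerate perimeter 0 and is excluded from roundness aggregates.
* **Convex hull and minimum-area rectangle** are computed over the *corner
  points* of the boundary pixels (each pixel treated as a unit square). This
  keeps the geometric chain ``area <= hull_area <= mbb_area <= bbox area``
  exact, and makes the rectangle sides of an axis-aligned n x m block equal
  n and m rather than n-1 and m-1.
* The orthogonal (axis-aligned) bounding box uses pixel extents
  ``max - min + 1`` per axis.

Holes inside an instance are ignored (outer contour only); an instance that
is not 8-connected is measured on its largest connected component with a
warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage

__all__ = [
    "InstanceRecord",
    "MORPH_TRAIT_NAMES",
    "trace_contour",
    "contour_perimeter",
    "instance_area",
    "instance_perimeter",
    "roundness",
    "orthogonal_bbox",
    "min_area_rect",
    "convex_hull_area",
    "measure_instances",
    "aggregate_morphology",
]

#: The 35 morphological traits, in catalog order.
MORPH_TRAIT_NAMES: tuple[str, ...] = (
    "Average Perimeter",
    "Maximum Perimeter",
    "STD_Perimeter",
    "CV_Perimeter",
    "Average Roundness",
    "Maximum Roundness",
    "STD_Roundness",
    "CV_Roundness",
    "Total Leaf Number",
    "Total Leaf Area",
    "Average Leaf Area",
    "Maximum Leaf Area",
    "STD_Area",
    "CV_Area",
    "Average length_ori",
    "Average width_ori",
    "c_max_ori",
    "h_max_ori",
    "Average Length",
    "Maximum Length",
    "STD_Length",
    "CV_Length",
    "Average Width",
    "Maximum Width",
    "STD_Width",
    "CV_Width",
    "Average MBB_Area",
    "MBB_Area",
    "STD_MBB_Area",
    "CV_MBB_Area",
    "Average Area/MBB_Area",
    "STD_Area/MBB_Area",
    "Average Perimeter/Area",
    "STD_Perimeter/Area",
    "Convex Hull Leaf Area",
)

# Moore neighborhood, clockwise starting at W, in (dr, dc)
_MOORE = (
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
)
_STEP = tuple(math.hypot(dr, dc) for dr, dc in _MOORE)


@dataclass
class InstanceRecord:
    """Geometry of one organ instance."""

    label: int
    area: float
    perimeter: float
    contour: np.ndarray  # (n, 2) boundary pixel centers as (row, col)
    ortho_length: float
    ortho_width: float
    mbb_length: float
    mbb_width: float
    mbb_area: float
    hull_area: float
    hull_vertices: np.ndarray  # (m, 2) hull polygon vertices as (x, y)
    roundness: float


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a connected region through pixel centers.

    Returns the closed Moore-trace cycle as an ``(n, 2)`` array of
    ``(row, col)`` vertices; the closing edge from the last vertex back to
    the first is implicit. Spur pixels are traversed twice, so the cycle
    length equals the out-and-back path for degenerate (1-pixel-wide) parts.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    if rows.size == 1:
        return np.array([[rows[0], cols[0]]])
    h, w = mask.shape
    start_i = np.lexsort((cols, rows))[0]  # topmost, then leftmost
    start = (int(rows[start_i]), int(cols[start_i]))

    def find_next(cur, b):
        for i in range(8):
            k = (b + i) % 8
            nr, nc = cur[0] + _MOORE[k][0], cur[1] + _MOORE[k][1]
            if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
                return (nr, nc), k
        return None, None

    contour = [start]
    nxt, k = find_next(start, 0)
    first_next = nxt
    cur, b = nxt, (k + 5) % 8
    contour.append(cur)
    limit = 4 * rows.size + 8
    while True:
        nxt, k = find_next(cur, b)
        if cur == start and nxt == first_next:
            break
        cur, b = nxt, (k + 5) % 8
        contour.append(cur)
        if len(contour) > limit:  # pragma: no cover - safety net
            raise RuntimeError("contour tracing failed to terminate")
    return np.array(contour[:-1] if contour[-1] == start else contour)


def contour_perimeter(contour: np.ndarray) -> float:
    """Length of the closed polygon through the traced contour vertices."""
    if len(contour) < 2:
        return 0.0
    closed = np.vstack([contour, contour[:1]])
    d = np.diff(closed.astype(float), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _label_mask(instance_map: np.ndarray, label: int) -> np.ndarray:
    mask = np.asarray(instance_map) == label
    if label < 1 or not mask.any():
        raise ValueError(f"label {label} not present in instance map")
    return mask


def instance_area(instance_map: np.ndarray, label: int) -> int:
    """Pixel count of the given instance label."""
    return int(_label_mask(instance_map, label).sum())


def _largest_component(mask: np.ndarray, label: int) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        warnings.warn(
            f"instance {label} is not 8-connected; measuring its largest component"
        )
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (int(np.argmax(sizes)) + 1)
    return mask

def instance_perimeter(instance_map: np.ndarray, label: int) -> float:
    """Moore-trace perimeter of the instance's outer contour."""
    mask = _largest_component(_label_mask(instance_map, label), label)
    return contour_perimeter(trace_contour(mask))


def roundness(area: float, perimeter: float) -> float:
    """Isoperimetric ratio 4*pi*A / P**2; NaN when the perimeter is degenerate."""
    if perimeter <= 0:
        return float("nan")
    return 4.0 * math.pi * area / perimeter**2


def orthogonal_bbox(instance_map: np.ndarray, label: int) -> tuple[int, int]:
    """Axis-aligned extents (max - min + 1); returns (length, width), length >= width."""
    rows, cols = np.nonzero(_label_mask(instance_map, label))
    dr = int(rows.max() - rows.min() + 1)
    dc = int(cols.max() - cols.min() + 1)
    return (max(dr, dc), min(dr, dc))


def min_area_rect(points: np.ndarray) -> tuple[float, float, float]:
    """Minimum-area enclosing rectangle of the convex hull of ``points``.

    ``points`` is an ``(n, 2)`` array of (x, y) vertices. Returns
    ``(length, width, area)`` with ``length >= width``; the optimum has a side
    collinear with a hull edge (rotating-calipers semantics). Degenerate
    inputs (collinear points) yield width 0 and area 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("min_area_rect requires at least one point")
    hull = shapely.MultiPoint(points).convex_hull
    if hull.geom_type == "Point":
        return (0.0, 0.0, 0.0)
    if hull.geom_type == "LineString":
        return (float(hull.length), 0.0, 0.0)
    # exact edge-orientation search: the optimum has a side collinear with a
    # hull edge (shapely's minimum_rotated_rectangle is not exactly minimal)
    verts = np.asarray(hull.exterior.coords)[:-1]
    edges = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    norms = np.hypot(edges[:, 0], edges[:, 1])
    u = edges[norms > 0] / norms[norms > 0, None]
    best = (np.inf, 0.0, 0.0)
    for ux, uy in u:
        proj_l = verts @ (ux, uy)
        proj_w = verts @ (-uy, ux)
        ext_l = float(proj_l.max() - proj_l.min())
        ext_w = float(proj_w.max() - proj_w.min())
        area = ext_l * ext_w
        if area < best[0]:
            best = (area, max(ext_l, ext_w), min(ext_l, ext_w))
    return (best[1], best[2], best[0])


def convex_hull_area(points: np.ndarray) -> float:
    """Shoelace area of the convex hull of an (n, 2) point set; 0 if degenerate."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 3:
        return 0.0
    hull = shapely.MultiPoint(points).convex_hull
    return float(hull.area) if hull.geom_type == "Polygon" else 0.0


def _corner_cloud(contour: np.ndarray) -> np.ndarray:
    """Pixel-corner points (x, y) of the contour pixels: each pixel ±0.5 both axes."""
    rc = np.unique(contour, axis=0).astype(float)
    xy = rc[:, ::-1]  # (col, row) -> (x, y)
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    return (xy[:, None, :] + offs[None, :, :]).reshape(-1, 2)


def measure_instance(instance_map: np.ndarray, label: int) -> InstanceRecord:
    """Measure one instance's full geometry record."""
    mask = _largest_component(_label_mask(instance_map, label), label)
    area = float(mask.sum())
    contour = trace_contour(mask)
    perimeter = contour_perimeter(contour)
    rows, cols = np.nonzero(mask)
    dr = float(rows.max() - rows.min() + 1)
    dc = float(cols.max() - cols.min() + 1)
    corners = _corner_cloud(contour)
    hull = shapely.MultiPoint(corners).convex_hull
    hull_area = float(hull.area)
    hull_vertices = np.asarray(hull.exterior.coords)[:-1]
    mbb_length, mbb_width, mbb_area = min_area_rect(corners)
    return InstanceRecord(
        label=int(label),
        area=area,
        perimeter=perimeter,
        contour=contour,
        ortho_length=max(dr, dc),
        ortho_width=min(dr, dc),
        mbb_length=mbb_length,
        mbb_width=mbb_width,
        mbb_area=mbb_area,
        hull_area=hull_area,
        hull_vertices=hull_vertices,
        roundness=roundness(area, perimeter),
    )


def measure_instances(instance_map: np.ndarray) -> list[InstanceRecord]:
    """Measure every instance (labels 1..N) in the map."""
    labels = np.unique(instance_map)
    return [measure_instance(instance_map, int(k)) for k in labels if k > 0]


def _std(values: np.ndarray) -> float:
    return float(np.std(values))  # population SD: dispersion is descriptive


def _amsc(values) -> tuple[float, float, float, float]:
    """(average, maximum, SD, CV) of a value list, NaNs excluded."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        nan = float("nan")
        return nan, nan, nan, nan
    avg = float(np.mean(values))
    sd = _std(values)
    cv = sd / avg if avg > 0 else float("nan")
    return avg, float(np.max(values)), sd, cv


def aggregate_morphology(instances: list[InstanceRecord]) -> dict[str, float]:
    """Aggregate per-instance geometry into the 35-trait morphological set.

    The trait names and order follow :data:`MORPH_TRAIT_NAMES`. An empty
    instance list yields count 0, zero totals, and NaN for every average,
    SD and CV.
    """
    nan = float("nan")
    out = dict.fromkeys(MORPH_TRAIT_NAMES, nan)
    out["Total Leaf Number"] = float(len(instances))
    if not instances:
        out["Total Leaf Area"] = 0.0
        out["Convex Hull Leaf Area"] = 0.0
        return out

    peri = [r.perimeter for r in instances]
    area = [r.area for r in instances]
    rnd = [r.roundness for r in instances]
    olen = [r.ortho_length for r in instances]
    owid = [r.ortho_width for r in instances]
    mlen = [r.mbb_length for r in instances]
    mwid = [r.mbb_width for r in instances]
    marea = [r.mbb_area for r in instances]

    (
        out["Average Perimeter"],
        out["Maximum Perimeter"],
        out["STD_Perimeter"],
        out["CV_Perimeter"],
    ) = _amsc(peri)
    (
        out["Average Roundness"],
        out["Maximum Roundness"],
        out["STD_Roundness"],
        out["CV_Roundness"],
    ) = _amsc(rnd)
    (
        out["Average Leaf Area"],
        out["Maximum Leaf Area"],
        out["STD_Area"],
        out["CV_Area"],
    ) = _amsc(area)
    out["Total Leaf Area"] = float(np.sum(area))
    out["Average length_ori"] = float(np.mean(olen))
    out["Average width_ori"] = float(np.mean(owid))
    out["c_max_ori"] = float(np.max(olen))
    out["h_max_ori"] = float(np.max(owid))
    (
        out["Average Length"],
        out["Maximum Length"],
        out["STD_Length"],
        out["CV_Length"],
    ) = _amsc(mlen)
    (
        out["Average Width"],
        out["Maximum Width"],
        out["STD_Width"],
        out["CV_Width"],
    ) = _amsc(mwid)
    (
        out["Average MBB_Area"],
        out["MBB_Area"],
        out["STD_MBB_Area"],
        out["CV_MBB_Area"],
    ) = _amsc(marea)

    # ratio traits: Average Area/MBB_Area averages per-instance ratios;
    # the STD variants divide the numerator's SD by the mean denominator;
    # Average Perimeter/Area is the ratio of plant-level means.
    ratio = [a / m for a, m in zip(area, marea) if m > 0]
    out["Average Area/MBB_Area"] = float(np.mean(ratio)) if ratio else nan
    mean_marea = float(np.mean(marea))
    mean_area = float(np.mean(area))
    out["STD_Area/MBB_Area"] = (
        _std(np.asarray(area)) / mean_marea if mean_marea > 0 else nan
    )
    out["Average Perimeter/Area"] = (
        float(np.mean(peri)) / mean_area if mean_area > 0 else nan
    )
    out["STD_Perimeter/Area"] = (
        _std(np.asarray(peri)) / mean_area if mean_area > 0 else nan
    )

    all_hull_pts = np.vstack([r.hull_vertices for r in instances])
    out["Convex Hull Leaf Area"] = convex_hull_area(all_hull_pts)
    return out
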