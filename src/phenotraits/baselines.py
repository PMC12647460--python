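"""Classical segmentation baselines: ExG + Otsu thresholding, K-means color
clustering, and connected-component instance extraction.

These reproduce the traditional methods the deep pipeline is compared
against: a vegetation index followed by a global threshold gives a
semantic plant/background mask, and connected components turn that mask
into instances. On scenes with touching organs the components merge, so the
baseline systematically under-counts — the classic failure mode these
methods exhibit.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .io_formats import relabel_contiguous

__all__ = [
    "exg_index",
    "rescale_to_u8",
    "otsu_threshold",
    "kmeans_segment",
    "connected_components",
    "segment_baseline",
]


def exg_index(image: np.ndarray) -> np.ndarray:
    """Excess-green index 2G - R - B per pixel, on 0-255 channels.

    Range [-510, 510]; high values indicate vegetation.
    """
    rgb = np.asarray(image, dtype=np.int32)
    return 2 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]


def rescale_to_u8(grid: np.ndarray) -> np.ndarray:
    """Affinely rescale an arbitrary grid to integers in [0, 255].

    A constant grid maps to all zeros.
    """
    grid = np.asarray(grid, dtype=np.float64)
    lo, hi = float(grid.min()), float(grid.max())
    if hi == lo:
        return np.zeros(grid.shape, dtype=np.uint8)
    return np.round((grid - lo) / (hi - lo) * 255.0).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> tuple[int, np.ndarray]:
    """Otsu's threshold over the 256-bin histogram of an integer [0,255] grid.

    Returns ``(threshold, mask)`` where the threshold maximizes the
    between-class variance (ties broken toward the lower threshold; the
    comparison is done in exact integer arithmetic) and
    ``mask = gray > threshold``. A constant image yields that value as the
    threshold, an empty foreground, and a warning.
    """
    gray = np.asarray(gray)
    if gray.min() < 0 or gray.max() > 255:
        raise ValueError("grid must be rescaled/shifted to integers in [0, 255]")
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256)
    if np.count_nonzero(hist) == 1:
        value = int(np.nonzero(hist)[0][0])
        warnings.warn("constant image: Otsu threshold degenerate, empty foreground")
        return value, np.zeros(gray.shape, dtype=np.uint8)
    counts = [int(c) for c in hist]
    total = sum(counts)
    total_sum = sum(v * c for v, c in enumerate(counts))
    # between-class variance ∝ (S1*w0 - S0*w1)^2 / (w0*w1); compared exactly
    best_t, best_num, best_den = 0, -1, 1
    w0 = 0
    s0 = 0
    for t in range(256):
        w0 += counts[t]
        s0 += t * counts[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        s1 = total_sum - s0
        num = (s1 * w0 - s0 * w1) ** 2
        den = w0 * w1
        if num * best_den > best_num * den:  # strict: ties keep the lower t
            best_t, best_num, best_den = t, num, den
    mask = (gray > best_t).astype(np.uint8)
    return best_t, mask


def kmeans_segment(
    image: np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Cluster pixels by RGB color with k-means (k-means++ seeding, Lloyd).

    Returns ``(cluster_map, plant_label)`` where ``cluster_map`` assigns every
    pixel a label in 1..k and ``plant_label`` is the cluster with the highest
    mean excess-green index. Deterministic for a fixed seed. If the image has
    fewer distinct colors than ``k``, ``k`` is reduced with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    image = np.asarray(image)
    pixels = image.reshape(-1, 3).astype(np.float64)
    n_distinct = len(np.unique(pixels, axis=0))
    if k > n_distinct:
        warnings.warn(f"k={k} exceeds {n_distinct} distinct colors; reducing")
        k = n_distinct
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=300,
                random_state=seed)
    labels = km.fit_predict(pixels)
    cluster_map = (labels + 1).reshape(image.shape[:2]).astype(np.int32)
    exg = exg_index(image).ravel()
    mean_exg = [exg[labels == c].mean() for c in range(k)]
    return cluster_map, int(np.argmax(mean_exg)) + 1


def connected_components(
    mask: np.ndarray, connectivity: int = 8, min_area: int = 20
) -> np.ndarray:
    """Label maximal connected foreground components as instances.

    Components are numbered 1..N in raster-scan order of their first pixel;
    components smaller than ``min_area`` pixels are dropped (default 20, to
    suppress salt noise).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = (
        np.ones((3, 3), dtype=int)
        if connectivity == 8
        else np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    lab, n = ndimage.label(np.asarray(mask) > 0, structure=structure)
    if n and min_area > 1:
        sizes = np.bincount(lab.ravel(), minlength=n + 1)
        lab[np.isin(lab, np.nonzero(sizes < min_area)[0])] = 0
    out, _ = relabel_contiguous(lab)
    return out


def segment_baseline(
    image: np.ndarray,
    method: str = "otsu",
    k: int = 3,
    seed: int = 0,
    connectivity: int = 8,
    min_area: int = 20,
) -> np.ndarray:
    """Run a classical baseline end to end: color -> mask -> instances.

    ``method`` is ``"otsu"`` (ExG index + Otsu threshold) or ``"kmeans"``
    (RGB k-means; the cluster with the highest mean ExG is the plant).
    """
    if method == "otsu":
        _, mask = otsu_threshold(rescale_to_u8(exg_index(image)))
    elif method == "kmeans":
        cluster_map, plant = kmeans_segment(image, k=k, seed=seed)
        mask = cluster_map == plant
    else:
        raise ValueError(f"unknown baseline method: {method!r}")
    return connected_components(mask, connectivity=connectivity, min_area=min_area)
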