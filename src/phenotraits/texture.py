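"""The 22 texture traits: 7 Hu moment invariants and 15 gray-gradient
co-occurrence matrix (GGCM) features.

Hu moments are computed on the binary organ support (the union of all
instances as a {0,1} density), so they describe the plant's silhouette:
central moments normalized by ``mu00^((p+q)/2 + 1)``, with the sign of phi7
preserved so mirror images are distinguishable. A grayscale-weighted variant
is available behind a flag.

The GGCM is the joint histogram of quantized gray level and quantized Sobel
gradient magnitude over organ pixels. Grayscale is ITU-R BT.601 luma
(0.299 R + 0.587 G + 0.114 B); before the 3x3 Sobel filter, background
pixels are replicated from the nearest organ pixel so the support boundary
does not inject spurious gradients. Gray is quantized linearly to 16 bins
over [0, 255], gradient magnitude to 16 bins over [0, max-in-support]. The
15 features are the canonical gray-gradient set, in fixed order; entropies
use the natural logarithm, variances are second central moments of the
marginals, and correlation is the normalized cross-correlation of the two
marginals (0 when either marginal is degenerate).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "HU_TRAIT_NAMES",
    "GGCM_TRAIT_NAMES",
    "TEXTURE_TRAIT_NAMES",
    "hu_moments",
    "gray_gradient_matrix",
    "ggcm_features",
    "texture_traits",
]

HU_TRAIT_NAMES: tuple[str, ...] = tuple(f"Hu_moment{i}" for i in range(1, 8))

#: The 15 gray-gradient co-occurrence features, in catalog order.
GGCM_TRAIT_NAMES: tuple[str, ...] = (
    "Small_Gradient_Dominance",
    "Large_Gradient_Dominance",
    "Gray_Asymmetry",
    "Gradient_Asymmetry",
    "Energy",
    "Gray_Mean",
    "Gradient_Mean",
    "Gray_Variance",
    "Gradient_Variance",
    "Correlation",
    "Gray_Entropy",
    "Gradient_Entropy",
    "Mixed_Entropy",
    "Inertia",
    "Inverse_Difference_Moment",
)

TEXTURE_TRAIT_NAMES: tuple[str, ...] = HU_TRAIT_NAMES + GGCM_TRAIT_NAMES


def _luma(image: np.ndarray) -> np.ndarray:
    rgb = np.asarray(image, dtype=np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def hu_moments(
    image: np.ndarray, instance_map: np.ndarray, grayscale_weighted: bool = False
) -> np.ndarray:
    """Hu invariants phi1..phi7 of the organ support.

    By default the density is the binary union support; with
    ``grayscale_weighted=True`` the luma values on the support are used as
    weights instead. Returns an array of 7 NaNs for an empty support.
    """
    instance_map = np.asarray(instance_map)
    mask = instance_map > 0
    if not mask.any():
        return np.full(7, np.nan)
    if grayscale_weighted:
        density = np.where(mask, _luma(image), 0.0)
    else:
        density = mask.astype(np.float64)
    mu = measure.moments_central(density)
    nu = measure.moments_normalized(mu)
    return measure.moments_hu(nu)


def gray_gradient_matrix(
    image: np.ndarray, instance_map: np.ndarray, bins: int = 16
) -> np.ndarray:
    """Normalized joint histogram of (gray bin, gradient bin) over organ pixels."""
    image = np.asarray(image)
    instance_map = np.asarray(instance_map)
    if image.shape[:2] != instance_map.shape:
        raise ValueError("image and instance map dimensions differ")
    mask = instance_map > 0
    if not mask.any():
        raise ValueError("no organ pixels in instance map")
    gray = _luma(image)
    # replicate each background pixel from its nearest organ pixel so Sobel
    # responses at the support boundary reflect organ texture only
    if not mask.all():
        idx = ndimage.distance_transform_edt(
            ~mask, return_distances=False, return_indices=True
        )
        gray = gray[tuple(idx)]
    gx = ndimage.sobel(gray, axis=1, mode="nearest")
    gy = ndimage.sobel(gray, axis=0, mode="nearest")
    grad = np.hypot(gx, gy)

    g = np.clip((gray[mask] / 256.0 * bins).astype(int), 0, bins - 1)
    gmax = float(grad[mask].max())
    if gmax > 0:
        s = np.clip((grad[mask] / gmax * bins).astype(int), 0, bins - 1)
    else:
        s = np.zeros(g.shape, dtype=int)
    hist = np.bincount(g * bins + s, minlength=bins * bins).reshape(bins, bins)
    return hist / hist.sum()


def ggcm_features(M: np.ndarray) -> dict[str, float]:
    """The 15 canonical gray-gradient features of a normalized GGCM.

    ``M[i, j]`` is the joint probability of gray bin ``i`` and gradient bin
    ``j``; rows and columns index gray and gradient respectively.
    """
    M = np.asarray(M, dtype=np.float64)
    if not np.isclose(M.sum(), 1.0, atol=1e-9):
        raise ValueError("GGCM must be normalized to sum 1")
    ng, ns = M.shape
    i = np.arange(ng, dtype=np.float64)[:, None]  # gray index
    j = np.arange(ns, dtype=np.float64)[None, :]  # gradient index
    px = M.sum(axis=1)  # gray marginal
    py = M.sum(axis=0)  # gradient marginal
    mu_g = float((np.arange(ng) * px).sum())
    mu_s = float((np.arange(ns) * py).sum())
    var_g = float(((np.arange(ng) - mu_g) ** 2 * px).sum())
    var_s = float(((np.arange(ns) - mu_s) ** 2 * py).sum())
    cov = float((((i - mu_g) * (j - mu_s)) * M).sum())

    def entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    out = {
        "Small_Gradient_Dominance": float((M / (j + 1.0) ** 2).sum()),
        "Large_Gradient_Dominance": float((M * j**2).sum()),
        "Gray_Asymmetry": float((px**2).sum()),
        "Gradient_Asymmetry": float((py**2).sum()),
        "Energy": float((M**2).sum()),
        "Gray_Mean": mu_g,
        "Gradient_Mean": mu_s,
        "Gray_Variance": var_g,
        "Gradient_Variance": var_s,
        "Correlation": (
            cov / np.sqrt(var_g * var_s) if var_g > 0 and var_s > 0 else 0.0
        ),
        "Gray_Entropy": entropy(px),
        "Gradient_Entropy": entropy(py),
        "Mixed_Entropy": entropy(M.ravel()),
        "Inertia": float(((i - j) ** 2 * M).sum()),
        "Inverse_Difference_Moment": float((M / (1.0 + (i - j) ** 2)).sum()),
    }
    return out


def texture_traits(image: np.ndarray, instance_map: np.ndarray) -> dict[str, float]:
    """All 22 texture traits in catalog order; NaN set for empty scenes."""
    mask = np.asarray(instance_map) > 0
    if not mask.any():
        return dict.fromkeys(TEXTURE_TRAIT_NAMES, float("nan"))
    hu = hu_moments(image, instance_map)
    out = {name: float(v) for name, v in zip(HU_TRAIT_NAMES, hu)}
    M = gray_gradient_matrix(image, instance_map)
    out.update(ggcm_features(M))
    return out
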