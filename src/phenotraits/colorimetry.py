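"""The 7 color traits: chromatic-coordinate statistics over organ pixels.

Each organ pixel's RGB triple is mapped to chromatic coordinates
``r = R/(R+G+B)``, ``g = G/(R+G+B)``, ``b = B/(R+G+B)``; a pure black pixel
contributes the simplex center (1/3, 1/3, 1/3). Traits are the mean and
population SD of each coordinate over the union of all instances, plus
``G_All_mean``, the whole-plant green proportion (identical to
``G_Ratio_mean`` by construction; the duplication keeps the 64-trait catalog
intact). All traits are invariant to global intensity scaling and to
instance relabeling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["COLOR_TRAIT_NAMES", "color_traits"]

#: The 7 color traits, in catalog order.
COLOR_TRAIT_NAMES: tuple[str, ...] = (
    "R_Ratio_mean",
    "STD_R_mean",
    "G_Ratio_mean",
    "STD_G_mean",
    "B_Ratio_mean",
    "STD_B_mean",
    "G_All_mean",
)


def color_traits(
    image: np.ndarray, instance_map: np.ndarray, include_raw: bool = False
) -> dict[str, float]:
    """Compute the 7 chromatic-ratio traits over all organ pixels.

    Parameters
    ----------
    image : (H, W, 3) uint8 RGB image.
    instance_map : (H, W) integer label map; organ pixels are ``> 0``.
    include_raw : if True, append auxiliary non-catalog columns with the raw
        0-255 per-channel means (``R_raw_mean`` etc.).

    Returns NaN for every trait when the scene has no organ pixels.
    """
    image = np.asarray(image)
    instance_map = np.asarray(instance_map)
    if image.shape[:2] != instance_map.shape:
        raise ValueError("image and instance map dimensions differ")
    mask = instance_map > 0
    nan = float("nan")
    out = dict.fromkeys(COLOR_TRAIT_NAMES, nan)
    if include_raw:
        for c in "RGB":
            out[f"{c}_raw_mean"] = nan
    if not mask.any():
        return out

    rgb = image[mask].astype(np.float64)
    total = rgb.sum(axis=1)
    chrom = np.where(
        total[:, None] > 0, rgb / np.where(total[:, None] > 0, total[:, None], 1.0), 1.0 / 3.0
    )
    means = chrom.mean(axis=0)
    stds = chrom.std(axis=0)  # population SD over pixels
    out["R_Ratio_mean"], out["G_Ratio_mean"], out["B_Ratio_mean"] = map(float, means)
    out["STD_R_mean"], out["STD_G_mean"], out["STD_B_mean"] = map(float, stds)
    out["G_All_mean"] = float(means[1])
    if include_raw:
        raw = rgb.mean(axis=0)
        out["R_raw_mean"], out["G_raw_mean"], out["B_raw_mean"] = map(float, raw)
    return out
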