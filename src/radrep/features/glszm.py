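"""Gray-level size-zone matrix (GLSZM) features.

A zone is a 26-connected component of in-mask voxels sharing one gray level;
the matrix is direction-free.  Sixteen features, mirroring the run-length
family with zone size in place of run length.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._common import entropy_bits

GLSZM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def zones(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All (gray level, zone size) pairs via 26-connected component labelling."""
    gray_list, size_list = [], []
    for g in np.unique(levels[mask]):
        sel = mask & (levels == g)
        lab, n = ndimage.label(sel, structure=_STRUCT_26)
        if n:
            sizes = np.bincount(lab[sel])[1:]
            gray_list.append(np.full(n, g))
            size_list.append(sizes)
    return np.concatenate(gray_list), np.concatenate(size_list)


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    gray, size = zones(levels, mask)
    nz = float(gray.size)
    n_voxels = int(mask.sum())
    g = gray.astype(np.float64)
    s = size.astype(np.float64)
    p = np.full(gray.size, 1.0 / nz)
    mu_g = float(np.sum(p * g))
    mu_s = float(np.sum(p * s))
    sum_g = np.bincount(gray)[1:]
    sum_g = sum_g[sum_g > 0].astype(np.float64)
    sum_s = np.bincount(size)[1:]
    sum_s = sum_s[sum_s > 0].astype(np.float64)
    pairs = gray.astype(np.int64) * (int(size.max()) + 1) + size
    counts = np.bincount(pairs)
    p_joint = counts[counts > 0] / nz

    return {
        "GrayLevelNonUniformity": float(np.sum(sum_g**2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(sum_g**2) / nz**2),
        "GrayLevelVariance": float(np.sum(p * (g - mu_g) ** 2)),
        "HighGrayLevelZoneEmphasis": float(np.sum(g**2) / nz),
        "LargeAreaEmphasis": float(np.sum(s**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(g**2 * s**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(s**2 / g**2) / nz),
        "LowGrayLevelZoneEmphasis": float(np.sum(1.0 / g**2) / nz),
        "SizeZoneNonUniformity": float(np.sum(sum_s**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(sum_s**2) / nz**2),
        "SmallAreaEmphasis": float(np.sum(1.0 / s**2) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(g**2 / s**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(1.0 / (g**2 * s**2)) / nz),
        "ZoneEntropy": entropy_bits(p_joint),
        "ZonePercentage": float(nz / n_voxels),
        "ZoneVariance": float(np.sum(p * (s - mu_s) ** 2)),
    }
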