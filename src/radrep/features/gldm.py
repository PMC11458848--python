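"""Gray-level dependence matrix (GLDM) features.

The dependence of a voxel is 1 plus the number of its 26-neighbours inside
the mask whose gray level differs by at most ``alpha`` (default 0, i.e.
equal levels).  Fourteen features over the (gray level, dependence) counts.
"""

from __future__ import annotations

import numpy as np

from ._common import DIRECTIONS_13, entropy_bits, shifted_slices

GLDM_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)


def dependence_counts(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Per-voxel dependence (1 + count of similar in-mask 26-neighbours)."""
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in DIRECTIONS_13:  # each unique direction covers both signs
        src, dst = shifted_slices(levels.shape, d)
        both = mask[src] & mask[dst]
        close = np.abs(levels[src] - levels[dst]) <= alpha
        hit = both & close
        dep[src] += hit
        dep[dst] += hit
    return dep + 1


def gldm_features(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> dict[str, float]:
    dep = dependence_counts(levels, mask, alpha)[mask]
    g = levels[mask].astype(np.float64)
    k = dep.astype(np.float64)
    nz = float(g.size)
    p = np.full(g.size, 1.0 / nz)
    mu_g = float(np.sum(p * g))
    mu_k = float(np.sum(p * k))
    sum_g = np.bincount(levels[mask])[1:]
    sum_g = sum_g[sum_g > 0].astype(np.float64)
    sum_k = np.bincount(dep)[1:]
    sum_k = sum_k[sum_k > 0].astype(np.float64)
    pairs = levels[mask].astype(np.int64) * (int(dep.max()) + 1) + dep
    counts = np.bincount(pairs)
    p_joint = counts[counts > 0] / nz

    return {
        "DependenceEntropy": entropy_bits(p_joint),
        "DependenceNonUniformity": float(np.sum(sum_k**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(sum_k**2) / nz**2),
        "DependenceVariance": float(np.sum(p * (k - mu_k) ** 2)),
        "GrayLevelNonUniformity": float(np.sum(sum_g**2) / nz),
        "GrayLevelVariance": float(np.sum(p * (g - mu_g) ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(g**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(k**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(g**2 * k**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(k**2 / g**2) / nz),
        "LowGrayLevelEmphasis": float(np.sum(1.0 / g**2) / nz),
        "SmallDependenceEmphasis": float(np.sum(1.0 / k**2) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(g**2 / k**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(1.0 / (g**2 * k**2)) / nz),
    }
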