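"""Neighbourhood gray-tone difference matrix (NGTDM) features.

For each in-mask voxel with at least one in-mask 26-neighbour, the absolute
difference between its gray level and the mean level of those neighbours is
accumulated per gray level (``s_i``).  Five features: Coarseness, Contrast,
Busyness, Complexity, Strength.

Degenerate conventions: a constant ROI has Contrast = Busyness = 0 and
Strength = 0 when all differences vanish; Coarseness is capped at 1e6 when
its denominator is zero (the established radiomics convention).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._common import neighbor_kernel

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

COARSENESS_CAP = 1e6


def ngtdm_table(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Returns (gray levels present, n_i counts, s_i sums, Nvp)."""
    kern = neighbor_kernel()
    m = mask.astype(np.float64)
    neigh_count = ndimage.correlate(m, kern, mode="constant", cval=0.0)
    neigh_sum = ndimage.correlate(levels * m, kern, mode="constant", cval=0.0)
    valid = mask & (neigh_count > 0.5)
    avg = neigh_sum[valid] / neigh_count[valid]
    g_vox = levels[valid]
    diff = np.abs(g_vox - avg)
    counts = np.bincount(g_vox)
    sums = np.bincount(g_vox, weights=diff)
    gray = np.nonzero(counts)[0]
    return gray.astype(np.float64), counts[gray].astype(np.float64), sums[gray], int(valid.sum())


def ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    gray, n_i, s_i, nvp = ngtdm_table(levels, mask)
    if nvp == 0:
        # isolated voxels only: no neighbourhood exists
        return {
            "Busyness": 0.0,
            "Coarseness": COARSENESS_CAP,
            "Complexity": 0.0,
            "Contrast": 0.0,
            "Strength": 0.0,
        }
    p_i = n_i / nvp
    ngp = gray.size
    gi = gray[:, None]
    gj = gray[None, :]
    pi = p_i[:, None]
    pj = p_i[None, :]

    denom_coarse = float(np.sum(p_i * s_i))
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    if ngp > 1:
        contrast = float(
            np.sum(pi * pj * (gi - gj) ** 2) / (ngp * (ngp - 1)) * (s_i.sum() / nvp)
        )
        busy_den = float(np.sum(np.abs(gi * pi - gj * pj)))
        busyness = denom_coarse / busy_den if busy_den > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0

    ps = (p_i * s_i)[:, None]
    complexity = float(np.sum(np.abs(gi - gj) * (ps + ps.T) / (pi + pj)) / nvp)

    s_sum = float(s_i.sum())
    strength = float(np.sum((pi + pj) * (gi - gj) ** 2) / s_sum) if s_sum > 0 else 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
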