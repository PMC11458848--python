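"""Shared helpers for the texture-matrix families.

All families operate on an integer ``levels`` grid (1-based inside the mask,
0 outside) and its boolean mask, at distance 1 with 26-connectivity.
Thirteen unique 3-D direction vectors cover all axis/diagonal neighbours up
to sign.
"""

from __future__ import annotations

import numpy as np

#: The 13 unique distance-1 direction vectors in 3-D (up to sign).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

assert len(DIRECTIONS_13) == 13


def crop_to_mask(levels: np.ndarray, mask: np.ndarray, pad: int = 0):
    """Crop levels/mask to the mask's bounding box (optionally padded)."""
    idx = np.nonzero(mask)
    lo = [max(int(i.min()) - pad, 0) for i in idx]
    hi = [min(int(i.max()) + 1 + pad, s) for i, s in zip(idx, mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return levels[sl], mask[sl]


def shifted_slices(shape, d):
    """Index slices (src, dst) so that ``arr[src]`` and ``arr[dst]`` are the
    voxel pairs separated by direction ``d``."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def direction_pairs(levels: np.ndarray, mask: np.ndarray, d):
    """Gray-level pairs (i, j) for all in-mask voxel pairs along direction d."""
    src, dst = shifted_slices(levels.shape, d)
    valid = mask[src] & mask[dst]
    return levels[src][valid], levels[dst][valid]


def neighbor_kernel() -> np.ndarray:
    """3x3x3 kernel of ones with a zero centre (the 26-neighbourhood)."""
    k = np.ones((3, 3, 3))
    k[1, 1, 1] = 0.0
    return k


def entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits over the positive entries of ``p``."""
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))
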