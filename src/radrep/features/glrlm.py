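"""Gray-level run-length matrix (GLRLM) features.

A run is a maximal set of consecutive in-mask voxels along one of the 13
unique 3-D directions sharing the same gray level; runs are truncated at the
mask boundary.  The 16 features are computed per direction and averaged.
"""

from __future__ import annotations

import numpy as np

from ._common import DIRECTIONS_13, entropy_bits

GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)


def mask_run_order(mask: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """Level-independent line ordering of the mask voxels for direction ``d``.

    Returns ``(flat_order, line_break)``: flat voxel indices sorted into
    digital lines ``p = base + t*d``, and a flag per consecutive pair marking
    a structural break (different line or a gap along it).
    """
    coords = np.argwhere(mask)
    flat = np.ravel_multi_index(tuple(coords.T), mask.shape)
    d = np.asarray(d)
    # signed position along the line, using the first axis where d is nonzero
    ax = int(np.nonzero(d)[0][0])
    t = coords[:, ax] * d[ax]
    base = coords - t[:, None] * d[None, :]
    order = np.lexsort((t, base[:, 2], base[:, 1], base[:, 0]))
    t, base = t[order], base[order]
    same_line = np.all(base[1:] == base[:-1], axis=1)
    line_break = ~same_line | (np.diff(t) != 1)
    return flat[order], line_break


def make_run_cache(mask: np.ndarray) -> dict:
    """Precompute the 13 per-direction orderings for one mask."""
    return {d: mask_run_order(mask, d) for d in DIRECTIONS_13}


def runs_in_direction(
    levels: np.ndarray, mask: np.ndarray, d, order=None
) -> tuple[np.ndarray, np.ndarray]:
    """All maximal runs along direction ``d``: returns (gray level, length) arrays.

    Mask voxels are sorted into digital lines; consecutive positions on a
    line with equal level form one run (runs truncate at the mask boundary).
    """
    if order is None:
        order = mask_run_order(mask, d)
    flat_order, line_break = order
    lv = levels.ravel()[flat_order]
    # a new run starts at a structural break or where the level changes
    new_run = np.empty(lv.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = line_break | (lv[1:] != lv[:-1])
    run_id = np.cumsum(new_run) - 1
    lengths = np.bincount(run_id)
    gray = lv[new_run]
    return gray, lengths


def _features_one(gray: np.ndarray, lengths: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = float(gray.size)
    g = gray.astype(np.float64)
    l = lengths.astype(np.float64)
    p = np.full(gray.size, 1.0 / nr)

    mu_g = float(np.sum(p * g))
    mu_l = float(np.sum(p * l))
    # marginal totals per distinct gray level / run length
    sum_g = np.bincount(gray)[1:]
    sum_g = sum_g[sum_g > 0].astype(np.float64)
    sum_l = np.bincount(lengths)[1:]
    sum_l = sum_l[sum_l > 0].astype(np.float64)

    return {
        "GrayLevelNonUniformity": float(np.sum(sum_g**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(sum_g**2) / nr**2),
        "GrayLevelVariance": float(np.sum(p * (g - mu_g) ** 2)),
        "HighGrayLevelRunEmphasis": float(np.sum(g**2) / nr),
        "LongRunEmphasis": float(np.sum(l**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(g**2 * l**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(l**2 / g**2) / nr),
        "LowGrayLevelRunEmphasis": float(np.sum(1.0 / g**2) / nr),
        "RunEntropy": _run_entropy(gray, lengths, nr),
        "RunLengthNonUniformity": float(np.sum(sum_l**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(sum_l**2) / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "RunVariance": float(np.sum(p * (l - mu_l) ** 2)),
        "ShortRunEmphasis": float(np.sum(1.0 / l**2) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(g**2 / l**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(1.0 / (g**2 * l**2)) / nr),
    }


def _run_entropy(gray: np.ndarray, lengths: np.ndarray, nr: float) -> float:
    # entropy of the joint (gray level, run length) distribution
    pairs = gray.astype(np.int64) * (int(lengths.max()) + 1) + lengths
    counts = np.bincount(pairs)
    p = counts[counts > 0] / nr
    return entropy_bits(p)


def glrlm_features(
    levels: np.ndarray, mask: np.ndarray, run_cache: dict | None = None
) -> dict[str, float]:
    """The 16 GLRLM features averaged over the 13 unique 3-D directions."""
    n_voxels = int(mask.sum())
    if run_cache is None:
        run_cache = make_run_cache(mask)
    per_dir = [
        _features_one(*runs_in_direction(levels, mask, d, run_cache[d]), n_voxels)
        for d in DIRECTIONS_13
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}
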