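"""Gray-level co-occurrence matrix (GLCM) features.

Symmetric co-occurrence matrices at distance 1 are built for each of the 13
unique 3-D directions; the 24 features are computed per direction and
averaged.  Matrices are restricted to the gray levels present in the ROI.

Degenerate conventions (single gray level): Contrast 0, Correlation 1,
Imc1/Imc2 0, MCC 1 — fixed so feature vectors are always complete.
"""

from __future__ import annotations

import numpy as np

from ._common import DIRECTIONS_13, direction_pairs, entropy_bits

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, direction) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric, normalized co-occurrence matrix for one direction.

    Returns ``(P, g)`` where ``g`` holds the distinct gray levels present in
    the ROI and ``P`` is the |g| x |g| probability matrix over those levels.
    A direction with no in-mask pairs yields a zero matrix.
    """
    g = np.unique(levels[mask])
    m = g.size
    lut = np.zeros(int(g.max()) + 1, dtype=np.int64)
    lut[g] = np.arange(m)
    i, j = direction_pairs(levels, mask, direction)
    P = np.zeros((m, m), dtype=np.float64)
    if i.size:
        np.add.at(P, (lut[i], lut[j]), 1.0)
        P = P + P.T  # symmetric
        P /= P.sum()
    return P, g.astype(np.float64)


def _features_one(P: np.ndarray, g: np.ndarray) -> dict[str, float]:
    m = g.size
    if P.sum() == 0:  # no pairs in this direction: treat as degenerate
        P = np.eye(m) / m
    gi = g[:, None]
    gj = g[None, :]
    px = P.sum(axis=1)
    mu = float(np.sum(px * g))
    sigma2 = float(np.sum(px * (g - mu) ** 2))

    diff = np.abs(gi - gj)
    # distributions over |i-j| and i+j (levels are integral)
    diff_i = diff.astype(np.int64)
    kd = np.arange(0, int(diff_i.max()) + 1)
    pd = np.bincount(diff_i.ravel(), weights=P.ravel())
    s_i = (gi + gj).astype(np.int64)
    ps_full = np.bincount(s_i.ravel(), weights=P.ravel())
    ks = np.nonzero(ps_full)[0]
    ps = ps_full[ks]
    if ks.size == 0:  # degenerate all-zero P cannot happen after guard
        ks, ps = np.array([0]), np.array([1.0])

    da = float(np.sum(kd * pd))
    hxy = entropy_bits(P.ravel())
    pxpy = px[:, None] * px[None, :]
    pos = P > 0
    hxy1 = float(-np.sum(P[pos] * np.log2(pxpy[pos]))) if np.all(pxpy[pos] > 0) else hxy
    hxy2 = entropy_bits(pxpy.ravel())
    hx = entropy_bits(px)

    ng = float(m)
    out: dict[str, float] = {}
    out["Autocorrelation"] = float(np.sum(P * gi * gj))
    ct = gi + gj - 2 * mu
    out["ClusterProminence"] = float(np.sum(P * ct**4))
    out["ClusterShade"] = float(np.sum(P * ct**3))
    out["ClusterTendency"] = float(np.sum(P * ct**2))
    out["Contrast"] = float(np.sum(P * (gi - gj) ** 2))
    if sigma2 > 0:
        out["Correlation"] = (out["Autocorrelation"] - mu**2) / sigma2
    else:
        out["Correlation"] = 1.0
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = entropy_bits(pd)
    out["DifferenceVariance"] = float(np.sum(pd * (kd - da) ** 2))
    out["Id"] = float(np.sum(P / (1.0 + diff)))
    out["Idm"] = float(np.sum(P / (1.0 + diff**2)))
    out["Idmn"] = float(np.sum(P / (1.0 + (diff / ng) ** 2)))
    out["Idn"] = float(np.sum(P / (1.0 + diff / ng)))
    # symmetric P => marginal entropies HX = HY
    if m == 1 or hx == 0:
        out["Imc1"] = 0.0
        out["Imc2"] = 0.0
    else:
        out["Imc1"] = (hxy - hxy1) / hx
        out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off = diff > 0
    out["InverseVariance"] = float(np.sum(P[off] / diff[off] ** 2)) if off.any() else 0.0
    out["JointAverage"] = mu
    out["JointEnergy"] = float(np.sum(P**2))
    out["JointEntropy"] = hxy
    if m == 1:
        out["MCC"] = 1.0
    else:
        # Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) px(k))  (symmetric P => py = px)
        safe_px = np.where(px > 0, px, 1.0)
        Q = (P / safe_px[:, None]) @ (P / safe_px[None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        second = ev[-2] if ev.size > 1 else ev[-1]
        out["MCC"] = float(np.sqrt(max(0.0, second)))
    out["MaximumProbability"] = float(P.max())
    out["SumAverage"] = float(np.sum(ks * ps))
    out["SumEntropy"] = entropy_bits(ps)
    out["SumSquares"] = float(np.sum(P * (gi - mu) ** 2))
    return out


def glcm_features_direction(levels: np.ndarray, mask: np.ndarray, direction) -> dict[str, float]:
    """The 24 GLCM features for a single direction (no averaging)."""
    return _features_one(*glcm_matrix(levels, mask, direction))


def glcm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """The 24 GLCM features, averaged over the 13 unique 3-D directions.

    Directions with no in-mask voxel pair (possible for very thin ROIs) are
    excluded from the average; a single-voxel ROI falls back to the
    degenerate single-level conventions.
    """
    per_dir = []
    for d in DIRECTIONS_13:
        P, g = glcm_matrix(levels, mask, d)
        if P.sum() > 0:
            per_dir.append(_features_one(P, g))
    if not per_dir:
        per_dir = [_features_one(*glcm_matrix(levels, mask, DIRECTIONS_13[0]))]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}
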