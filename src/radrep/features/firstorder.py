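"""First-order (intensity-statistic) features.

Eighteen statistics of the ROI gray values.  Most are functions of the raw
intensities; ``Entropy`` and ``Uniformity`` are computed on the discretized
gray levels and therefore depend on the bin width.  Conventions for
degenerate input: a constant ROI has skewness and kurtosis 0.
"""

from __future__ import annotations

import numpy as np

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    roi_values: np.ndarray, levels: np.ndarray, voxel_volume: float
) -> dict[str, float]:
    """Compute the 18 first-order features.

    Parameters
    ----------
    roi_values : 1-D array of ROI intensities (raw or filter-response).
    levels : 1-D array of discretized gray levels for the same voxels.
    voxel_volume : voxel volume in mm^3 (for TotalEnergy).
    """
    x = np.asarray(roi_values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("ROI is empty")
    lv = np.asarray(levels).ravel()
    n = x.size

    mean = x.mean()
    centered = x - mean
    m2 = np.mean(centered**2)
    m3 = np.mean(centered**3)
    m4 = np.mean(centered**4)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    energy = float(np.sum(x**2))

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0

    counts = np.bincount(lv)[1:]  # levels are 1-based
    p = counts[counts > 0] / n

    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(centered))),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
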