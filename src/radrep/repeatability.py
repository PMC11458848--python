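"""Repeatability scoring: one-way random-effects absolute-agreement ICC of
every feature across the original and perturbed extractions, the median-ICC
split into high/low-repeatable groups, and per-filter/bin-width/family
summaries.

The one-way model treats the original extraction and the p perturbed
realizations as k = p + 1 exchangeable repeated measurements of each patient
(there is no rater structure under perturbation):

    ICC = (MSB - MSW) / (MSB + (k - 1) MSW)

with MSB/MSW the between/within-subject mean squares of a one-way ANOVA.
Raw ICC may be negative; reported values are clamped to [0, 1].  A feature
with zero variance everywhere (MSB = MSW = 0) is perfectly repeatable by
convention (ICC = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features.engine import FeatureID

__all__ = [
    "RepeatabilityTable",
    "RepeatabilityGroups",
    "icc_one_way",
    "icc_one_way_matrix",
    "compute_feature_icc",
    "split_by_median_icc",
    "summarize_icc",
]


@dataclass(frozen=True)
class RepeatabilityTable:
    """Feature id -> clamped ICC, with the design size that produced it."""

    icc: pd.Series  # index: feature id strings, values in [0, 1]
    n_subjects: int
    n_repeats: int

    def __post_init__(self) -> None:
        if ((self.icc < 0) | (self.icc > 1)).any():
            raise ValueError("ICC values must lie in [0, 1]")


@dataclass(frozen=True)
class RepeatabilityGroups:
    """The median-ICC partition into high/low-repeatable feature groups."""

    cutoff: float
    high: tuple[str, ...]
    low: tuple[str, ...]


def icc_one_way(measurements: np.ndarray) -> tuple[float, float]:
    """One-way, random, absolute-agreement ICC of an n x k matrix.

    Returns ``(raw, clamped)``; ``raw`` may be negative (down to -1/(k-1)),
    ``clamped`` lies in [0, 1].  All-identical input gives 1 by convention.
    """
    x = np.asarray(measurements, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 subjects, k >= 2 repeats")
    if not np.all(np.isfinite(x)):
        raise ValueError("measurements must be finite")
    raw, clamped = icc_one_way_matrix(x[None, :, :])
    return float(raw[0]), float(clamped[0])


def icc_one_way_matrix(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ICC over a stack of f feature matrices (f, n, k)."""
    stack = np.asarray(stack, dtype=np.float64)
    f, n, k = stack.shape
    subj_mean = stack.mean(axis=2)  # (f, n)
    grand = stack.mean(axis=(1, 2))  # (f,)
    msb = k * ((subj_mean - grand[:, None]) ** 2).sum(axis=1) / (n - 1)
    msw = ((stack - subj_mean[:, :, None]) ** 2).sum(axis=(1, 2)) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    raw = np.where(denom > 0, (msb - msw) / np.where(denom > 0, denom, 1.0), 1.0)
    return raw, np.clip(raw, 0.0, 1.0)


def compute_feature_icc(
    original: pd.DataFrame, perturbed: list[pd.DataFrame]
) -> RepeatabilityTable:
    """Per-feature ICC across [original, perturbed_1 ... perturbed_p].

    All tables must share patients (rows) and feature ids (columns); each
    feature is scored with subjects = patients and k = p + 1 repeats.
    """
    if not perturbed:
        raise ValueError("need at least one perturbed feature table")
    for t in perturbed:
        if not t.index.equals(original.index) or not t.columns.equals(original.columns):
            raise ValueError("original and perturbed tables must share patients and features")
    stack = np.stack([original.to_numpy()] + [t.to_numpy() for t in perturbed], axis=2)
    # reorder to (features, subjects, repeats)
    stack = np.moveaxis(stack, 1, 0)
    _, clamped = icc_one_way_matrix(stack)
    icc = pd.Series(clamped, index=original.columns, name="icc")
    return RepeatabilityTable(icc=icc, n_subjects=original.shape[0], n_repeats=len(perturbed) + 1)


def split_by_median_icc(
    table: RepeatabilityTable, eligible: list[str] | None = None
) -> RepeatabilityGroups:
    """Split features at the median ICC into equally sized high/low groups.

    The cutoff is the median ICC of the eligible features.  Ties at the
    cutoff are resolved deterministically: features sorted by (ICC, id) and
    split at the midpoint, so group sizes differ by at most one.
    """
    icc = table.icc if eligible is None else table.icc.loc[eligible]
    if icc.size < 2:
        raise ValueError("need at least 2 eligible features to split")
    cutoff = float(icc.median())
    order = sorted(zip(icc.to_numpy(), icc.index.astype(str)))
    half = len(order) // 2
    low = tuple(fid for _, fid in order[:half])
    high = tuple(fid for _, fid in order[half:])
    return RepeatabilityGroups(cutoff=cutoff, high=high, low=low)


_GROUP_KEYS = ("filter", "bin_width", "family")


def summarize_icc(table: RepeatabilityTable, group_by: str) -> pd.DataFrame:
    """Median/mean/quartile ICC per filter, bin width, or feature family."""
    if group_by not in _GROUP_KEYS:
        raise KeyError(f"group_by must be one of {_GROUP_KEYS}")
    parsed = [FeatureID.parse(fid) for fid in table.icc.index]
    keys = {
        "filter": [p.filter_name for p in parsed],
        "bin_width": [p.bin_width for p in parsed],
        "family": [p.family for p in parsed],
    }[group_by]
    df = pd.DataFrame({"key": keys, "icc": table.icc.to_numpy()})
    out = df.groupby("key")["icc"].agg(
        median="median",
        mean="mean",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        n="size",
    )
    out.index.name = group_by
    return out
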