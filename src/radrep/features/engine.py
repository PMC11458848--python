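"""Feature-extraction engine: enumerates the filter bank x bin widths x
feature families and assembles complete, canonically ordered feature
vectors.

The default configuration yields 93 features (18 first-order + 24 GLCM +
16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM) per filtered image and bin width:
93 x 14 x 5 = 6510 values per ROI.  Feature identifiers follow the
``<filter>_bw<width>_<family>_<name>`` scheme so grouping by filter, bin
width or family is a string parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure

from ..datatypes import ImageVolume, ROIMask
from ..preprocess import (
    DEFAULT_BIN_WIDTHS,
    DEFAULT_WINDOW,
    FilterSpec,
    default_filter_specs,
    discretize,
    filter_bank,
)
from ._common import crop_to_mask
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .glcm import GLCM_NAMES, glcm_features
from .gldm import GLDM_NAMES, gldm_features
from .glrlm import GLRLM_NAMES, glrlm_features
from .glszm import GLSZM_NAMES, glszm_features
from .ngtdm import NGTDM_NAMES, ngtdm_features

__all__ = [
    "FeatureID",
    "ExtractionConfig",
    "FAMILY_NAMES",
    "extract_all",
    "extract_table",
    "mesh_volume",
]

FAMILY_NAMES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

N_FEATURES_PER_CONFIG = sum(len(v) for v in FAMILY_NAMES.values())  # 93


@dataclass(frozen=True, order=True)
class FeatureID:
    """Structured identity of one radiomic feature value."""

    filter_name: str
    bin_width: float
    family: str
    name: str

    def __str__(self) -> str:
        return f"{self.filter_name}_bw{self.bin_width:g}_{self.family}_{self.name}"

    @classmethod
    def parse(cls, text: str) -> "FeatureID":
        filter_name, bw, family, name = text.split("_", 3)
        if not bw.startswith("bw"):
            raise ValueError(f"malformed feature id {text!r}")
        return cls(filter_name, float(bw[2:]), family, name)


@dataclass(frozen=True)
class ExtractionConfig:
    """What to extract: filter bank, bin widths, families, window."""

    filters: tuple[FilterSpec, ...] = tuple(default_filter_specs())
    bin_widths: tuple[float, ...] = DEFAULT_BIN_WIDTHS
    families: tuple[str, ...] = tuple(FAMILY_NAMES)
    window: tuple[float, float] | None = DEFAULT_WINDOW
    wavelet: str = "coif1"
    gldm_alpha: int = 0

    def feature_ids(self) -> list[FeatureID]:
        """Canonical, stable enumeration of every configured FeatureID."""
        ids = []
        for spec in self.filters:
            for w in self.bin_widths:
                for family in self.families:
                    for name in FAMILY_NAMES[family]:
                        ids.append(FeatureID(spec.name, float(w), family, name))
        return ids

    @property
    def n_features(self) -> int:
        return (
            len(self.filters)
            * len(self.bin_widths)
            * sum(len(FAMILY_NAMES[f]) for f in self.families)
        )


def mesh_volume(mask: ROIMask) -> float:
    """ROI volume (mm^3) of the marching-cubes isosurface at level 0.5.

    The binary grid is zero-padded so masks touching the grid edge close
    properly; the enclosed volume comes from the divergence theorem applied
    to the triangulation.
    """
    mask.check_nonempty()
    padded = np.pad(mask.values.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return float(abs(mesh.volume))


def _family_values(
    family: str,
    roi_values: np.ndarray,
    levels_grid: np.ndarray,
    levels_roi: np.ndarray,
    mask: np.ndarray,
    voxel_volume: float,
    gldm_alpha: int,
    run_cache: dict | None = None,
) -> dict[str, float]:
    if family == "firstorder":
        return first_order_features(roi_values, levels_roi, voxel_volume)
    if family == "glcm":
        return glcm_features(levels_grid, mask)
    if family == "glrlm":
        return glrlm_features(levels_grid, mask, run_cache=run_cache)
    if family == "glszm":
        return glszm_features(levels_grid, mask)
    if family == "gldm":
        return gldm_features(levels_grid, mask, alpha=gldm_alpha)
    if family == "ngtdm":
        return ngtdm_features(levels_grid, mask)
    raise ValueError(f"unknown feature family {family!r}")


def extract_all(
    volume: ImageVolume, mask: ROIMask, config: ExtractionConfig | None = None
) -> dict[FeatureID, float]:
    """Extract the full configured feature vector for one (image, mask) pair.

    Inputs are expected prepped (isotropically resampled); the display
    window is applied internally to the original-image branch only.  Returns
    a complete mapping over :meth:`ExtractionConfig.feature_ids` with finite
    values; any family failure aborts with the offending FeatureID.
    """
    if config is None:
        config = ExtractionConfig()
    mask.check_nonempty()
    if not mask.matches(volume):
        raise ValueError("mask geometry does not match image")

    images = filter_bank(
        volume, list(config.filters), window=config.window, wavelet=config.wavelet
    )
    out: dict[FeatureID, float] = {}
    run_cache = None
    for spec in config.filters:
        img = images[spec.name]
        values_crop, mask_crop = crop_to_mask(img.values, mask.values, pad=1)
        if run_cache is None and "glrlm" in config.families:
            from .glrlm import make_run_cache

            run_cache = make_run_cache(mask_crop)
        roi_values = values_crop[mask_crop]
        for w in config.bin_widths:
            levels_roi = discretize(roi_values, w)
            levels_grid = np.zeros(values_crop.shape, dtype=np.int64)
            levels_grid[mask_crop] = levels_roi
            for family in config.families:
                vals = _family_values(
                    family,
                    roi_values,
                    levels_grid,
                    levels_roi,
                    mask_crop,
                    volume.voxel_volume,
                    config.gldm_alpha,
                    run_cache=run_cache,
                )
                for name in FAMILY_NAMES[family]:
                    fid = FeatureID(spec.name, float(w), family, name)
                    v = vals[name]
                    if not np.isfinite(v):
                        raise ArithmeticError(f"non-finite value for {fid}")
                    out[fid] = float(v)
    return out


def extract_table(cases, config: ExtractionConfig | None = None):
    """Extract features for an iterable of ``(patient_id, volume, mask)``.

    Returns a pandas DataFrame (patients x features) with canonical column
    order and string feature ids as columns.
    """
    import pandas as pd

    if config is None:
        config = ExtractionConfig()
    fids = config.feature_ids()
    columns = [str(fid) for fid in fids]
    rows, index = [], []
    for pid, volume, roi in cases:
        vec = extract_all(volume, roi, config)
        rows.append([vec[fid] for fid in fids])
        index.append(pid)
    return pd.DataFrame(rows, index=index, columns=columns)
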