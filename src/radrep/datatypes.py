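"""Core in-memory containers for volumetric images and region-of-interest masks.

Axis convention
---------------
Arrays are indexed ``(z, y, x)``: axis 0 is the craniocaudal (slice) axis and
axes 1-2 span the axial plane.  ``spacing`` gives the physical voxel pitch in
millimetres per array axis, in the same order.  All geometric operations in
the package (resampling, rotation, supervoxels, mesh volume) interpret arrays
through this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageVolume", "ROIMask"]


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar grid (HU or filter-response units) with physical geometry.

    Parameters
    ----------
    values : ndarray
        3-D float array, finite everywhere.
    spacing : tuple of float
        Voxel pitch in mm per array axis ``(z, y, x)``; strictly positive.
    origin : tuple of float
        Physical coordinate (mm) of the voxel at index ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"values must be 3-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """Same geometry, new scalar field (filters use this)."""
        return replace(self, values=values)


@dataclass(frozen=True)
class ROIMask:
    """Binary 3-D mask sharing the geometry of an :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {values.shape}")
        if values.dtype != bool:
            uniq = np.unique(values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask must be binary")
            values = values.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def check_nonempty(self) -> "ROIMask":
        if self.voxel_count == 0:
            raise ValueError("ROI mask is empty")
        return self

    def matches(self, image: ImageVolume) -> bool:
        return self.shape == image.shape and np.allclose(self.spacing, image.spacing)

    def with_values(self, values: np.ndarray) -> "ROIMask":
        return replace(self, values=values)
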