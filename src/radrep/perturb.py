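"""Image/contour perturbation: simulated re-measurement of a tumor ROI.

Two sources of spatial variability are emulated: small rigid rotations of
image + mask (patient posture / scanning angle) and supervoxel-based contour
randomization (delineation imprecision).  One perturbation realization is a
rotation by an angle drawn from the configured range followed by contour
randomization of the rotated mask.  Feature values recomputed on these
perturbed copies feed the ICC repeatability analysis.

All operations are pure: inputs are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import slic

from .datatypes import ImageVolume, ROIMask

__all__ = [
    "PerturbationSpec",
    "PerturbedPair",
    "rotate_pair",
    "build_supervoxels",
    "contour_randomize",
    "generate_perturbation_set",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PerturbationSpec:
    """Parameters of the perturbation chain.

    ``rotation_range_deg`` bounds the uniform axial rotation angle (about the
    craniocaudal axis, array axis 0); ``supervoxel_target_volume`` is the
    expected supervoxel size in mm^3; ``n_realizations`` perturbed copies are
    generated per case.
    """

    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    n_realizations: int = 10
    supervoxel_target_volume: float = 64.0
    randomize_contour: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.supervoxel_target_volume <= 0:
            raise ValueError("supervoxel_target_volume must be > 0")
        lo, hi = self.rotation_range_deg
        if lo > hi:
            raise ValueError("rotation_range_deg must be (low, high)")

    @classmethod
    def identity(cls, n_realizations: int = 1) -> "PerturbationSpec":
        """A spec that leaves every copy identical to the input."""
        return cls(rotation_range_deg=(0.0, 0.0), n_realizations=n_realizations,
                   randomize_contour=False)


@dataclass(frozen=True)
class PerturbedPair:
    """One perturbed (image, mask) realization with its provenance."""

    image: ImageVolume
    mask: ROIMask
    realization: int
    angle_deg: float
    contour_seed: int | None


def rotate_pair(
    volume: ImageVolume,
    mask: ROIMask,
    angle_deg: float,
    axis: int = 0,
    center: np.ndarray | None = None,
) -> tuple[ImageVolume, ROIMask]:
    """Rotate image (trilinear) and mask (nearest-neighbour) jointly.

    Rotation is about ``axis`` through ``center`` (voxel coordinates;
    defaults to the mask centroid), output stays on the original grid.
    Angles are guarded to |angle| <= 30 degrees: larger values are no longer
    a plausible positioning perturbation.
    """
    if abs(angle_deg) > 30.0:
        raise ValueError("|angle_deg| must be <= 30 for a positioning perturbation")
    mask.check_nonempty()
    if angle_deg == 0.0:
        return volume.with_values(volume.values.copy()), mask.with_values(mask.values.copy())
    sp = volume.spacing
    plane = [ax for ax in range(3) if ax != axis]
    if not np.isclose(sp[plane[0]], sp[plane[1]]):
        raise ValueError("rotation plane must have isotropic spacing")
    if center is None:
        center = ndimage.center_of_mass(mask.values)
    center = np.asarray(center, dtype=np.float64)

    theta = np.deg2rad(angle_deg)
    rot = np.eye(3)
    a, b = plane
    rot[a, a] = np.cos(theta)
    rot[a, b] = -np.sin(theta)
    rot[b, a] = np.sin(theta)
    rot[b, b] = np.cos(theta)
    # affine_transform maps output coords to input coords: x_in = R^-1 (x_out - c) + c
    inv = rot.T
    offset = center - inv @ center
    new_img = ndimage.affine_transform(volume.values, inv, offset=offset, order=1, mode="nearest")
    new_msk = ndimage.affine_transform(
        mask.values.astype(np.uint8), inv, offset=offset, order=0, mode="constant", cval=0
    ).astype(bool)
    if not new_msk.any():
        raise ValueError("rotation emptied the ROI mask")
    return volume.with_values(new_img), mask.with_values(new_msk)


def build_supervoxels(
    volume: ImageVolume,
    mask: ROIMask,
    target_volume_mm3: float = 64.0,
    seed: int = 0,
    dilation_vox: int = 3,
    compactness: float = 0.05,
) -> np.ndarray:
    """SLIC supervoxels over the mask's dilated bounding region.

    Labels are positive inside the region and 0 outside; the expected
    supervoxel volume is ``target_volume_mm3``.  SLIC's grid initialisation
    makes the result deterministic; ``seed`` is kept for provenance.
    """
    mask.check_nonempty()
    region = ndimage.binary_dilation(mask.values, structure=_STRUCT_26, iterations=dilation_vox)
    region_volume = float(region.sum()) * mask.voxel_volume
    if target_volume_mm3 > region_volume:
        raise ValueError(
            f"supervoxel target volume {target_volume_mm3} mm^3 exceeds region volume "
            f"{region_volume:.0f} mm^3"
        )
    n_segments = max(int(round(region_volume / target_volume_mm3)), 1)
    scale = np.ptp(volume.values[region])
    img = volume.values if scale == 0 else (volume.values - volume.values[region].min()) / max(scale, 1e-12)
    labels = slic(
        img,
        n_segments=n_segments,
        compactness=compactness,
        mask=region,
        channel_axis=None,
        start_label=1,
        enforce_connectivity=True,
    )
    return labels


def contour_randomize(
    mask: ROIMask,
    supervoxels: np.ndarray,
    seed: int = 0,
    max_retries: int = 10,
) -> ROIMask:
    """Redraw the contour by sampling supervoxels by their mask overlap.

    Each supervoxel with overlap fraction f is included independently with
    probability f (so the expected redrawn volume equals the original);
    whole supervoxels (f = 1) are always kept, disjoint ones (f = 0) never.
    The result is restricted to its largest 26-connected component.  An
    empty draw is retried with a derived sub-seed, then raises.
    """
    mask.check_nonempty()
    if not ((supervoxels > 0) | ~mask.values).all():
        raise ValueError("supervoxel labels do not cover the mask")
    sizes = np.bincount(supervoxels.ravel())
    overlap = np.bincount(supervoxels[mask.values].ravel(), minlength=sizes.size)
    frac = np.zeros(sizes.size)
    nonzero = sizes > 0
    frac[nonzero] = overlap[nonzero] / sizes[nonzero]

    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(attempt,)))
        include = rng.random(sizes.size) < frac  # f=0 never, f=1 always
        include[frac >= 1.0] = True
        new_mask = include[supervoxels]
        new_mask &= supervoxels > 0
        if not new_mask.any():
            continue
        lab, n = ndimage.label(new_mask, structure=_STRUCT_26)
        if n > 1:
            largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
            new_mask = lab == largest
        return mask.with_values(new_mask)
    raise RuntimeError(f"contour randomization produced an empty mask after {max_retries} tries")


def generate_perturbation_set(
    volume: ImageVolume, mask: ROIMask, spec: PerturbationSpec
) -> list[PerturbedPair]:
    """Generate ``spec.n_realizations`` perturbed copies of (volume, mask).

    Each realization draws a rotation angle uniformly from the spec's range,
    rotates image and mask jointly, then (optionally) randomizes the rotated
    contour with supervoxels built on the rotated image.  Fully
    deterministic for a fixed spec.
    """
    mask.check_nonempty()
    pairs: list[PerturbedPair] = []
    lo, hi = spec.rotation_range_deg
    for r in range(spec.n_realizations):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(r,)))
        angle = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        img_r, msk_r = rotate_pair(volume, mask, angle)
        contour_seed = None
        if spec.randomize_contour:
            contour_seed = int(rng.integers(0, 2**31 - 1))
            sv = build_supervoxels(img_r, msk_r, spec.supervoxel_target_volume, seed=contour_seed)
            msk_r = contour_randomize(msk_r, sv, seed=contour_seed)
        pairs.append(PerturbedPair(img_r, msk_r, r, angle, contour_seed))
    return pairs
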