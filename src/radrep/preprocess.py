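"""Image preprocessing: windowing, isotropic resampling, the LoG/wavelet
filter bank, and fixed-bin-width gray-level discretization.

The preprocessing chain mirrors standard CT radiomics practice: volumes are
clamped to a mediastinal display window, resampled to 1 x 1 x 1 mm, passed
through a bank of 14 filters (original + 5 Laplacian-of-Gaussian scales +
8 one-level wavelet sub-bands), and ROI gray values are discretized with a
fixed bin width anchored at the ROI minimum before texture-matrix
computation.

Filters are applied to the *unwindowed* resampled volume: LoG and wavelet
responses are signed band-pass signals that HU clamping would destroy.  The
window is applied only to the original-image branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .datatypes import ImageVolume, ROIMask

__all__ = [
    "FilterSpec",
    "DiscretizationSpec",
    "WAVELET_SUBBANDS",
    "DEFAULT_LOG_SIGMAS_MM",
    "DEFAULT_BIN_WIDTHS",
    "apply_window",
    "resample_isotropic",
    "log_filter",
    "wavelet_decompose",
    "discretize",
    "filter_bank",
    "default_filter_specs",
]

#: Sub-band labels for a one-level separable 3-D wavelet decomposition,
#: L = low-pass, H = high-pass, ordered along array axes (z, y, x).
WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

#: Default LoG scales (mm).  The filter bank uses five scales.
DEFAULT_LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0)

#: Default fixed bin widths (HU or filter-response units).
DEFAULT_BIN_WIDTHS = (8.0, 16.0, 32.0, 64.0, 128.0)

#: Default mediastinal window (level, width) in HU.
DEFAULT_WINDOW = (40.0, 400.0)

#: Default wavelet family (the de-facto radiomics choice).
DEFAULT_WAVELET = "coif1"


@dataclass(frozen=True)
class FilterSpec:
    """Identity of one image in the filter bank.

    ``kind`` is ``original``, ``log`` or ``wavelet``; ``sigma_mm`` applies to
    LoG only and ``subband`` to wavelet only.  The default bank enumerates
    exactly 14 identities: 1 original + 5 LoG + 8 wavelet.
    """

    kind: str
    sigma_mm: float | None = None
    subband: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("original", "log", "wavelet"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "log" and (self.sigma_mm is None or self.sigma_mm <= 0):
            raise ValueError("LoG filter requires sigma_mm > 0")
        if self.kind == "wavelet" and self.subband not in WAVELET_SUBBANDS:
            raise ValueError(f"wavelet filter requires subband in {WAVELET_SUBBANDS}")

    @property
    def name(self) -> str:
        if self.kind == "original":
            return "original"
        if self.kind == "log":
            sigma = f"{self.sigma_mm:g}"
            return f"log-sigma-{sigma}mm"
        return f"wavelet-{self.subband}"


def default_filter_specs(
    log_sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM,
) -> list[FilterSpec]:
    """The canonical 14-image filter bank specification."""
    specs = [FilterSpec("original")]
    specs += [FilterSpec("log", sigma_mm=s) for s in log_sigmas_mm]
    specs += [FilterSpec("wavelet", subband=b) for b in WAVELET_SUBBANDS]
    return specs


@dataclass(frozen=True)
class DiscretizationSpec:
    """Fixed-bin-width discretization, anchored at the ROI minimum."""

    bin_width: float

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


def apply_window(volume: ImageVolume, level: float = 40.0, width: float = 400.0) -> ImageVolume:
    """Clamp HU values to the display window ``[level - width/2, level + width/2]``."""
    if width <= 0:
        raise ValueError("window width must be > 0")
    lo, hi = level - width / 2.0, level + width / 2.0
    return volume.with_values(np.clip(volume.values, lo, hi))


def resample_isotropic(
    volume: ImageVolume,
    mask: ROIMask | None = None,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ImageVolume | tuple[ImageVolume, ROIMask]:
    """Resample image (trilinear) and mask (nearest-neighbour) to a target spacing.

    Output spacing is exactly ``target_spacing``; output shape is chosen so the
    physical extent is preserved to within one voxel.  A mask that becomes
    empty after resampling raises.
    """
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")
    if mask is not None and not mask.matches(volume):
        raise ValueError("mask geometry does not match image")

    zoom = tuple(s / t for s, t in zip(volume.spacing, target))
    if np.allclose(zoom, 1.0):
        out_img = ImageVolume(volume.values.copy(), target, volume.origin)
        if mask is None:
            return out_img
        return out_img, ROIMask(mask.values.copy(), target, mask.origin)

    new_values = ndimage.zoom(volume.values, zoom, order=1, mode="nearest", grid_mode=True)
    out_img = ImageVolume(new_values, target, volume.origin)
    if mask is None:
        return out_img
    new_mask = ndimage.zoom(mask.values.astype(np.uint8), zoom, order=0, mode="nearest", grid_mode=True)
    out_mask = ROIMask(new_mask.astype(bool), target, mask.origin)
    if out_mask.voxel_count == 0:
        raise ValueError("ROI mask is empty after resampling")
    return out_img, out_mask


def log_filter(volume: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Scale-normalized Laplacian-of-Gaussian response at scale ``sigma_mm``.

    The response is ``sigma^2 * (Laplacian of Gaussian-smoothed image)`` so
    magnitudes are comparable across scales.  Requires isotropic spacing.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be > 0")
    sp = volume.spacing
    if not np.allclose(sp, sp[0]):
        raise ValueError("log_filter requires isotropic spacing; resample first")
    sigma_vox = sigma_mm / sp[0]
    if sigma_vox < 1.0:
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is below one voxel ({sp[0]} mm); response is noisy",
            stacklevel=2,
        )
    response = ndimage.gaussian_laplace(volume.values, sigma=sigma_vox, mode="nearest")
    return volume.with_values(sigma_mm**2 * response)


def _subband_key(subband: str) -> str:
    # pywt labels low/high pass 'a'/'d' per axis, in array-axis order.
    return subband.replace("L", "a").replace("H", "d").lower()


def wavelet_decompose(
    volume: ImageVolume, wavelet: str = DEFAULT_WAVELET
) -> dict[str, ImageVolume]:
    """One-level separable 3-D wavelet decomposition into 8 sub-band images.

    Each sub-band is reconstructed back onto the original grid (all other
    sub-bands zeroed before the inverse transform), so every output shares
    the input geometry and the eight reconstructions sum to the original
    image (perfect reconstruction).
    """
    wav = pywt.Wavelet(wavelet)
    shape = volume.values.shape
    if min(shape) < wav.dec_len:
        raise ValueError(
            f"grid dimension {min(shape)} smaller than wavelet filter length {wav.dec_len}"
        )
    coeffs = pywt.dwtn(volume.values, wav, mode="symmetric")
    out: dict[str, ImageVolume] = {}
    for band in WAVELET_SUBBANDS:
        key = _subband_key(band)
        only = {k: (v if k == key else np.zeros_like(v)) for k, v in coeffs.items()}
        rec = pywt.idwtn(only, wav, mode="symmetric")
        rec = rec[tuple(slice(0, n) for n in shape)]  # idwtn may pad odd axes
        out[band] = volume.with_values(rec)
    return out


def discretize(roi_values: np.ndarray, spec: DiscretizationSpec | float) -> np.ndarray:
    """Fixed-bin-width gray-level discretization of ROI intensities.

    ``level(x) = floor((x - min) / w) + 1``, giving integer levels ``1..Ng``
    anchored at the ROI minimum (hence invariant to adding a constant).
    """
    if not isinstance(spec, DiscretizationSpec):
        spec = DiscretizationSpec(float(spec))
    x = np.asarray(roi_values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("roi_values is empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("roi_values must be finite")
    levels = np.floor((x - x.min()) / spec.bin_width).astype(np.int64) + 1
    return levels


def filter_bank(
    volume: ImageVolume,
    specs: list[FilterSpec] | None = None,
    *,
    window: tuple[float, float] | None = DEFAULT_WINDOW,
    wavelet: str = DEFAULT_WAVELET,
) -> dict[str, ImageVolume]:
    """Compute the named filter-bank images for a prepped (isotropic) volume.

    The window (level, width) is applied to the original branch only; LoG and
    wavelet filters see the unwindowed volume.  Returns a dict keyed by
    :attr:`FilterSpec.name` preserving the spec order.
    """
    if specs is None:
        specs = default_filter_specs()
    wavelet_cache: dict[str, ImageVolume] | None = None
    out: dict[str, ImageVolume] = {}
    for spec in specs:
        if spec.kind == "original":
            img = volume
            if window is not None:
                img = apply_window(volume, *window)
            out[spec.name] = img
        elif spec.kind == "log":
            out[spec.name] = log_filter(volume, spec.sigma_mm)
        else:
            if wavelet_cache is None:
                wavelet_cache = wavelet_decompose(volume, wavelet)
            out[spec.name] = wavelet_cache[spec.subband]
    return out
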