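"""File I/O: NIfTI image/mask pairs, cohort CSV tables, YAML manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datatypes import ImageVolume, ROIMask

__all__ = [
    "save_nifti",
    "load_nifti_image",
    "load_nifti_mask",
    "save_cohort",
    "load_table",
    "save_yaml",
    "load_yaml",
    "save_json",
]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_nifti(obj: ImageVolume | ROIMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = obj.values.astype(np.uint8) if isinstance(obj, ROIMask) else obj.values
    nib.save(nib.Nifti1Image(data, _affine(obj.spacing, obj.origin)), str(path))
    return path


def _load(path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return data, spacing, origin


def load_nifti_image(path: str | Path) -> ImageVolume:
    data, spacing, origin = _load(path)
    return ImageVolume(data.astype(np.float64), spacing, origin)


def load_nifti_mask(path: str | Path) -> ROIMask:
    data, spacing, origin = _load(path)
    return ROIMask(data > 0.5, spacing, origin)


def save_cohort(cohort, out_dir: str | Path) -> Path:
    """Write a synthetic cohort: NIfTI pairs, clinical+survival CSV, manifest."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for pid, (img, msk) in cohort.images.items():
        save_nifti(img, out / "images" / f"{pid}_image.nii.gz")
        save_nifti(msk, out / "images" / f"{pid}_mask.nii.gz")
    cohort.table.to_csv(out / "cohort.csv", index_label="patient_id")
    save_yaml(cohort.manifest, out / "manifest.yaml")
    return out


def load_table(path: str | Path, index_col: str = "patient_id") -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def save_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_plain(obj), sort_keys=False))
    return path


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_plain(obj), indent=2, sort_keys=True))
    return path


def _plain(obj):
    """Recursively convert numpy/pandas scalars and containers to plain python."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return _plain(obj.to_dict())
    return obj
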