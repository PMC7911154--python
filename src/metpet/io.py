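"""NIfTI-1 volume I/O (nibabel) with voxel spacing in the header.

Phantoms are axis-aligned: the affine is diagonal with the voxel spacing,
no orientation handling.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .segmentation import ActivityVolume, DoseInfo

__all__ = ["save_volume", "load_volume", "load_activity_volume", "load_dose_info"]


def save_volume(values: np.ndarray, voxel_spacing, path: str | Path) -> Path:
    """Write a 3D array as NIfTI-1 with a diagonal affine from the spacing."""
    path = Path(path)
    affine = np.diag(list(voxel_spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(values), affine)
    img.header.set_zooms(tuple(float(s) for s in voxel_spacing))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI-1 volume; returns (values, voxel spacing in mm)."""
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {values.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return values, spacing


def load_activity_volume(path: str | Path) -> ActivityVolume:
    values, spacing = load_volume(path)
    return ActivityVolume(values=values, voxel_spacing=spacing)


def load_dose_info(sidecar_path: str | Path) -> DoseInfo:
    """Dose/weight from a JSON sidecar (keys body_weight_g, injected_dose_bq)."""
    payload = json.loads(Path(sidecar_path).read_text())
    return DoseInfo(
        body_weight_g=float(payload["body_weight_g"]),
        injected_dose_bq=float(payload["injected_dose_bq"]),
    )
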