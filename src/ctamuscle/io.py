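"""NIfTI volume/mask and CSV table round-trips.

Volumes are stored as int16 HU NIfTI-1 with voxel spacing in the affine;
masks as uint8 {0,1}.  The z axis (array axis 2) is the knee->ankle axis
throughout the package.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import CTVolume
from .segmentation import MuscleMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_table",
    "write_table",
    "ensure_dir",
]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def _spacing_from(img) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    if any(s <= 0 for s in z):
        raise ValueError(f"non-positive voxel spacing in header: {z}")
    return tuple(float(s) for s in z)


def write_volume(path, volume: CTVolume) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.hu.astype(np.int16), _affine(volume.spacing))
    img.header.set_data_dtype(np.int16)
    nib.save(img, path)
    return path


def read_volume(path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    return CTVolume(hu=data.astype(np.int16), spacing=_spacing_from(img))


def write_mask(path, mask: MuscleMask) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.spacing))
    img.header.set_data_dtype(np.uint8)
    nib.save(img, path)
    return path


def read_mask(path) -> MuscleMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    vals = np.unique(data)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError(f"mask is not binary; values found: {vals[:10]}")
    m = MuscleMask(mask=data.astype(bool), spacing=_spacing_from(img))
    m.z_range = (0, data.shape[2] - 1)
    return m


def write_table(path, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path, required_columns=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"table {path} is missing columns: {missing}")
    return df
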