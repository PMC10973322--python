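"""Threshold-based lower-leg muscle segmentation with structural cleanup.

Muscle is separated from fat, cortical bone and contrast-filled arteries by
an HU window (default [-10, 100], both bounds inclusive).  Two in-window
interference tissues survive thresholding and are removed by deterministic
structural rules standing in for the manual correction step of a
semi-automatic workflow:

* marrow: in-window components fully enclosed, per slice, by voxels at or
  above a cortical-bone HU floor;
* veins/noise: 3D connected components below a minimum size, then per slice
  everything except the largest in-plane component and components at least
  10% of its size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import CTVolume

__all__ = [
    "SegmentationParams",
    "MuscleMask",
    "threshold_segment",
    "clean_mask",
    "restrict_z",
    "segment_muscle",
]

#: 26-connectivity in 3D
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)
#: 8-connectivity in 2D
_STRUCT_2D = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    hu_low: float = -10.0
    hu_high: float = 100.0
    min_component_voxels: int = 50
    bone_hu_min: float = 300.0

    def __post_init__(self) -> None:
        if self.hu_low >= self.hu_high:
            raise ValueError(f"hu_low ({self.hu_low}) must be < hu_high ({self.hu_high})")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")


@dataclass
class MuscleMask:
    """Binary ROI aligned to a CTVolume; axis 2 runs knee -> ankle."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    z_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def threshold_segment(volume: CTVolume, params: SegmentationParams | None = None) -> np.ndarray:
    """Raw window mask: voxel selected iff hu_low <= HU <= hu_high (inclusive)."""
    params = params or SegmentationParams()
    hu = volume.hu
    return (hu >= params.hu_low) & (hu <= params.hu_high)


def _enclosed_by_bone(raw_slice: np.ndarray, bone_slice: np.ndarray) -> np.ndarray:
    """In-window 2D components with no path to the slice border avoiding bone.

    Equivalent to a flood fill from the border over non-bone voxels: whatever
    in-window region the fill cannot reach is enclosed (marrow analog).
    """
    free = ~bone_slice
    # label non-bone regions; any region touching the border is "outside"
    lab, n = ndimage.label(free, structure=_STRUCT_2D)
    if n == 0:
        return np.zeros_like(raw_slice)
    border = np.zeros_like(free)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    outside = np.unique(lab[border & free])
    reach = np.isin(lab, outside[outside > 0])
    return raw_slice & free & ~reach


def clean_mask(
    raw: np.ndarray,
    volume: CTVolume,
    params: SegmentationParams | None = None,
) -> MuscleMask:
    """Remove marrow-like enclosed regions and small/vein components."""
    params = params or SegmentationParams()
    raw = np.asarray(raw).astype(bool)
    if raw.shape != volume.hu.shape:
        raise ValueError("raw mask shape does not match volume")
    out = raw.copy()
    bone = volume.hu >= params.bone_hu_min

    # (a) per-slice bone-enclosed in-window regions (marrow)
    for z in range(out.shape[2]):
        enc = _enclosed_by_bone(out[:, :, z], bone[:, :, z])
        out[:, :, z] &= ~enc

    # (b) small 3D components (veins, noise)
    lab, n = ndimage.label(out, structure=_STRUCT_3D)
    if n:
        sizes = np.bincount(lab.ravel())
        small = sizes < params.min_component_voxels
        small[0] = False
        out[small[lab]] = False

    # per-slice retention: largest 2D component plus those >= 10% of it
    for z in range(out.shape[2]):
        sl = out[:, :, z]
        if not sl.any():
            continue
        lab2, n2 = ndimage.label(sl, structure=_STRUCT_2D)
        sizes = np.bincount(lab2.ravel())
        sizes[0] = 0
        keep = sizes >= 0.10 * sizes.max()
        keep[0] = False
        out[:, :, z] = keep[lab2]

    if not out.any():
        raise ValueError("no muscle found: cleaned mask is empty")
    return MuscleMask(mask=out, spacing=volume.spacing, z_range=(0, out.shape[2] - 1))


def restrict_z(mask: MuscleMask, z_start: int, z_end: int) -> MuscleMask:
    """Clear voxels outside the inclusive slice interval [z_start, z_end]."""
    nz = mask.mask.shape[2]
    if not (0 <= z_start <= z_end < nz):
        raise ValueError(f"invalid z interval [{z_start}, {z_end}] for nz={nz}")
    out = np.zeros_like(mask.mask)
    out[:, :, z_start : z_end + 1] = mask.mask[:, :, z_start : z_end + 1]
    return MuscleMask(mask=out, spacing=mask.spacing, z_range=(z_start, z_end))


def segment_muscle(
    volume: CTVolume,
    params: SegmentationParams | None = None,
    z_start: int | None = None,
    z_end: int | None = None,
) -> MuscleMask:
    """Full segmentation: threshold, clean, optionally restrict to a z range."""
    params = params or SegmentationParams()
    m = clean_mask(threshold_segment(volume, params), volume, params)
    if z_start is not None or z_end is not None:
        m = restrict_z(
            m,
            z_start if z_start is not None else 0,
            z_end if z_end is not None else volume.hu.shape[2] - 1,
        )
    return m
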