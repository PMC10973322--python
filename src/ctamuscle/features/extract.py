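"""Assemble the full feature vector: 95 intensity/texture + 16 shape values."""

from __future__ import annotations

import numpy as np

from .discretization import DiscretizationParams
from .histogram import HISTOGRAM_FEATURES, histogram_features
from .shape import SHAPE_FEATURES, shape_features
from .texture import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "INTENSITY_TEXTURE_FEATURES",
    "ALL_FEATURES",
    "FEATURE_FAMILIES",
    "extract_all",
    "extract_features",
]

INTENSITY_TEXTURE_FEATURES = (
    HISTOGRAM_FEATURES
    + GLCM_FEATURES
    + GLDM_FEATURES
    + GLRLM_FEATURES
    + GLSZM_FEATURES
    + NGTDM_FEATURES
)
ALL_FEATURES = INTENSITY_TEXTURE_FEATURES + SHAPE_FEATURES

FEATURE_FAMILIES = {
    "histogram": HISTOGRAM_FEATURES,
    "glcm": GLCM_FEATURES,
    "gldm": GLDM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "shape": SHAPE_FEATURES,
}

assert len(INTENSITY_TEXTURE_FEATURES) == 95
assert len(SHAPE_FEATURES) == 16


def extract_all(
    volume,
    mask,
    disc: DiscretizationParams | None = None,
    include_shape: bool = True,
) -> dict[str, float]:
    """Compute every feature for one (volume, mask) pair.

    Returns an ordered name -> value map with exactly 95 intensity/texture
    entries, plus 16 ``shape_*`` entries unless ``include_shape=False``.
    """
    disc = disc or DiscretizationParams()
    m = np.asarray(mask.mask if hasattr(mask, "mask") else mask, dtype=bool)
    hu = volume.hu if hasattr(volume, "hu") else np.asarray(volume)
    if m.shape != hu.shape:
        raise ValueError("mask shape does not match volume")
    if not m.any():
        raise ValueError("empty mask")

    out: dict[str, float] = {}
    out.update(histogram_features(hu[m], bin_width=disc.bin_width))
    out.update(glcm_features(volume, m, disc))
    out.update(gldm_features(volume, m, disc))
    out.update(glrlm_features(volume, m, disc))
    out.update(glszm_features(volume, m, disc))
    out.update(ngtdm_features(volume, m, disc))
    if include_shape:
        spacing = getattr(mask, "spacing", None) or getattr(volume, "spacing", (1.0, 1.0, 1.0))
        out.update(shape_features(m, spacing))
    expected = ALL_FEATURES if include_shape else INTENSITY_TEXTURE_FEATURES
    return {k: out[k] for k in expected}


_FAMILY_FN = {
    "histogram": lambda vol, m, disc: histogram_features(
        (vol.hu if hasattr(vol, "hu") else np.asarray(vol))[m], bin_width=disc.bin_width
    ),
    "glcm": glcm_features,
    "gldm": gldm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
    "shape": lambda vol, m, disc: shape_features(
        m, getattr(vol, "spacing", (1.0, 1.0, 1.0))
    ),
}


def extract_features(volume, mask, names, disc: DiscretizationParams | None = None) -> dict[str, float]:
    """Compute only the named features (whole families are computed at once)."""
    disc = disc or DiscretizationParams()
    m = np.asarray(mask.mask if hasattr(mask, "mask") else mask, dtype=bool)
    unknown = [n for n in names if n not in ALL_FEATURES]
    if unknown:
        raise ValueError(f"unknown features: {unknown}")
    out: dict[str, float] = {}
    for family in {n.split("_", 1)[0] for n in names}:
        out.update(_FAMILY_FN[family](volume, m, disc))
    return {n: out[n] for n in names}
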