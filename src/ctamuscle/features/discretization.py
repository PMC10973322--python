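"""Gray-level discretization and direction sets for texture matrices.

Intensities are re-binned with a fixed bin width anchored at the ROI
minimum: level(x) = floor((x - min) / width) + 1, giving integer levels
1..Ng.  Texture matrices are computed in 3D over 13 unique directions
(one per +/- pair of the 26-neighborhood) at distance 1 by default; a 2D
mode restricts directions and neighborhoods to the axial plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizationParams", "discretize", "ANGLES_3D", "ANGLES_2D"]


def _unique_directions(dims: int) -> list[tuple[int, ...]]:
    """One representative of each +/- offset pair of the unit neighborhood."""
    out = []
    rng = (-1, 0, 1)
    for off in np.stack(np.meshgrid(*[rng] * dims, indexing="ij"), -1).reshape(-1, dims):
        t = tuple(int(v) for v in off)
        if t == (0,) * dims:
            continue
        if tuple(-v for v in t) in out:
            continue
        out.append(t)
    return out


#: 13 unique 3D directions (axis order x, y, z)
ANGLES_3D: list[tuple[int, int, int]] = _unique_directions(3)
#: 4 unique in-plane directions, expressed as 3D offsets with dz = 0
ANGLES_2D: list[tuple[int, int, int]] = [
    (dx, dy, 0) for (dx, dy) in _unique_directions(2)
]


@dataclass(frozen=True)
class DiscretizationParams:
    """Gray-level binning and neighborhood geometry for texture features."""

    bin_width: float = 5.0
    distance: int = 1
    mode: str = "3d"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.mode not in ("3d", "2d"):
            raise ValueError(f"mode must be '3d' or '2d', got {self.mode!r}")

    @property
    def angles(self) -> list[tuple[int, int, int]]:
        base = ANGLES_3D if self.mode == "3d" else ANGLES_2D
        return [tuple(self.distance * v for v in a) for a in base]

    @property
    def neighborhood(self) -> list[tuple[int, int, int]]:
        """Full +/- neighborhood (26 offsets in 3D, 8 in-plane in 2D)."""
        full = []
        for a in self.angles:
            full.append(a)
            full.append(tuple(-v for v in a))
        return full


def discretize(hu: np.ndarray, mask: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Map masked intensities to integer levels 1..Ng; 0 outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(hu, dtype=float)
    lo = vals[mask].min()
    levels = np.zeros(vals.shape, dtype=np.int64)
    levels[mask] = np.floor((vals[mask] - lo) / bin_width).astype(np.int64) + 1
    return levels, int(levels.max())
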