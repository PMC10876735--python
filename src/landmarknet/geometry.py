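"""Voxel geometry and voxel <-> millimetre coordinate mapping.

Axes are ordered ``(z, y, x)`` = (slice, row, column) throughout the
package.  Voxel indices are 0-based and refer to voxel centres, so the
mapping to physical space is the affine ``mm = origin + index * spacing``
with the slice spacing along z and the in-plane pixel spacing along y
and x.  Patient-orientation matrices are out of scope: phantoms and
evaluation only need a consistent metric space in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGeometry", "voxel_to_mm", "mm_to_voxel"]


@dataclass(frozen=True)
class VoxelGeometry:
    """Metric description of a regular voxel grid.

    Parameters
    ----------
    in_plane_spacing : (float, float)
        mm per pixel along (y, x).  Stored separately per axis because
        anisotropic acquisition matrices resample to 256x256 with two
        different factors.
    slice_spacing : float
        mm between slice centres along z.
    origin : (float, float, float)
        mm position of the centre of voxel (0, 0, 0), ordered (z, y, x).
    """

    in_plane_spacing: tuple[float, float] = (1.0, 1.0)
    slice_spacing: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        sy, sx = self.in_plane_spacing
        if not (sy > 0 and sx > 0 and self.slice_spacing > 0):
            raise ValueError("voxel spacings must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis spacing in mm, ordered (z, y, x)."""
        sy, sx = self.in_plane_spacing
        return np.array([self.slice_spacing, sy, sx], dtype=float)

    def with_in_plane_spacing(self, spacing: tuple[float, float]) -> "VoxelGeometry":
        return VoxelGeometry(tuple(spacing), self.slice_spacing, self.origin)


def voxel_to_mm(geometry: VoxelGeometry, index) -> np.ndarray:
    """Map voxel indices (z, y, x) to mm positions.

    Accepts a single index triple or an (n, 3) array; fractional indices
    are allowed (sub-voxel positions interpolate the affine).
    """
    idx = np.asarray(index, dtype=float)
    return np.asarray(geometry.origin, dtype=float) + idx * geometry.spacing


def mm_to_voxel(geometry: VoxelGeometry, position) -> np.ndarray:
    """Inverse of :func:`voxel_to_mm`; returns fractional voxel indices."""
    pos = np.asarray(position, dtype=float)
    return (pos - np.asarray(geometry.origin, dtype=float)) / geometry.spacing
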