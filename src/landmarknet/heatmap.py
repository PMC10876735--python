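"""Gaussian heatmap targets and landmark extraction.

Landmark detection is phrased as heatmap regression: instead of
predicting coordinates directly, the network regresses, per landmark, a
temperature field

    t(v) = k * exp(-sum_d (v_d - p_d)^2 / (2 * sigma_d^2))

peaked at the landmark voxel p with peak temperature k (default 10^3 —
a large k stabilises early training against the near-zero background)
and per-axis standard deviation sigma_d of one voxel extent, which makes
the exponent dimensionless in index units and resolution-adaptive.

The predicted landmark is the argmax voxel.  When the maximum is
attained at several voxels, the tie is broken by the score S: the sum of
the heatmap over the 7x7x7 neighbourhood centred on the candidate
(clipped at the volume boundary), and any remaining tie by the
lexicographically smallest index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VoxelGeometry

__all__ = [
    "HeatmapConfig",
    "HeatmapVolume",
    "make_heatmap",
    "extract_landmark",
    "round_trip",
    "coarse_to_fine",
    "fine_to_coarse",
    "annotation_to_heatmaps",
]

#: half-width of the tie-break window: S sums over +-3 voxels per axis.
S_WINDOW_HALF = 3


@dataclass(frozen=True)
class HeatmapConfig:
    """Peak temperature ``k`` and per-axis standard deviation in voxels."""

    k: float = 1e3
    sigma: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("peak temperature k must be positive")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma must be positive along every axis")


@dataclass
class HeatmapVolume:
    """Per-landmark temperature grid at head output resolution."""

    values: np.ndarray
    landmark_id: int
    grid_geometry: VoxelGeometry | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("heatmap must be 3D")


def make_heatmap(
    landmark,
    grid_shape: tuple[int, int, int],
    config: HeatmapConfig = HeatmapConfig(),
    landmark_id: int = 1,
    grid_geometry: VoxelGeometry | None = None,
) -> HeatmapVolume:
    """Evaluate the Gaussian target on the full grid.

    ``landmark`` is a (z, y, x) position on the target grid (fractional
    positions allowed).
    """
    p = np.asarray(landmark, dtype=float)
    if p.shape != (3,):
        raise ValueError("landmark must be a (z, y, x) triple")
    upper = np.asarray(grid_shape, dtype=float)
    if np.any(p < 0) or np.any(p > upper - 1):
        raise ValueError(f"landmark {tuple(p)} outside grid {grid_shape}")
    axes = [
        ((np.arange(n, dtype=float) - p[d]) / config.sigma[d]) ** 2
        for d, n in enumerate(grid_shape)
    ]
    exponent = (
        axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    )
    values = config.k * np.exp(-exponent / 2.0)
    return HeatmapVolume(values=values, landmark_id=landmark_id,
                         grid_geometry=grid_geometry)


def _neighbourhood_sums(values: np.ndarray, half: int = S_WINDOW_HALF) -> np.ndarray:
    """Sum of ``values`` over the (2*half+1)^3 box around each voxel.

    Boundary windows are clipped at the volume edge, computed via a
    zero-padded summed-area construction (cumulative sums), which is
    equivalent to clipping for the sum.
    """
    w = 2 * half + 1
    out = values.astype(np.float64)
    for axis in range(3):
        pad_shape = list(out.shape)
        pad_shape[axis] = w - 1
        padded = np.concatenate(
            [np.zeros(pad_shape), out, np.zeros(pad_shape)], axis=axis
        )
        csum = np.cumsum(padded, axis=axis)
        n = values.shape[axis]
        hi = [slice(None)] * 3
        lo = [slice(None)] * 3
        hi[axis] = slice(w - 1 + half, w - 1 + half + n)
        lo[axis] = slice(half - 1, half - 1 + n) if half >= 1 else None
        upper = csum[tuple(hi)]
        lower = csum[tuple(lo)]
        out = upper - lower
    return out


def extract_landmark(heatmap: HeatmapVolume | np.ndarray) -> tuple[int, int, int]:
    """Argmax voxel, tie-broken by the 7x7x7 neighbourhood-sum score S."""
    values = heatmap.values if isinstance(heatmap, HeatmapVolume) else np.asarray(heatmap)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("heatmap contains no finite values")
    vmax = np.nanmax(np.where(finite, values, -np.inf))
    candidates = np.argwhere(values == vmax)
    if len(candidates) == 1:
        return tuple(int(c) for c in candidates[0])
    scores = _neighbourhood_sums(np.where(finite, values, 0.0))
    cand_scores = scores[tuple(candidates.T)]
    best = cand_scores == cand_scores.max()
    # candidates from argwhere are already in lexicographic order
    winner = candidates[best][0]
    return tuple(int(c) for c in winner)


def round_trip(
    landmark, grid_shape: tuple[int, int, int], config: HeatmapConfig = HeatmapConfig()
) -> tuple[int, int, int]:
    """``extract_landmark(make_heatmap(p))`` — identity for voxel-aligned p."""
    return extract_landmark(make_heatmap(landmark, grid_shape, config))


def coarse_to_fine(coarse, factor: int = 4) -> np.ndarray:
    """Map a coarse-grid index to the fine grid (block-centre convention).

    The head output grid downsamples the 256x256 plane by ``factor``;
    a coarse in-plane index c covers fine pixels [factor*c, factor*(c+1))
    whose centre is factor*c + (factor-1)/2.  Slice index is unchanged.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    c = np.asarray(coarse, dtype=float)
    out = c.copy()
    out[..., 1:] = factor * c[..., 1:] + (factor - 1) / 2.0
    return out


def fine_to_coarse(fine, factor: int = 4) -> np.ndarray:
    """Nearest coarse-grid index for a fine-grid position (inverse of
    :func:`coarse_to_fine` up to rounding)."""
    f = np.asarray(fine, dtype=float)
    out = f.copy()
    out[..., 1:] = (f[..., 1:] - (factor - 1) / 2.0) / factor
    return np.rint(out)


def annotation_to_heatmaps(
    landmarks: np.ndarray,
    grid_shape: tuple[int, int, int],
    factor: int = 4,
    config: HeatmapConfig = HeatmapConfig(),
) -> np.ndarray:
    """Build the 7 training targets on the head output grid.

    ``landmarks`` are (7, 3) voxel positions on the canonical fine grid;
    in-plane indices are mapped to the coarse grid and rounded to the
    nearest voxel.  Returns an array of shape (7,) + grid_shape.
    """
    coarse = fine_to_coarse(landmarks, factor=factor)
    coarse = np.clip(coarse, 0, np.asarray(grid_shape, dtype=float) - 1)
    out = np.empty((len(landmarks),) + tuple(grid_shape), dtype=np.float32)
    for j, p in enumerate(coarse):
        out[j] = make_heatmap(p, grid_shape, config, landmark_id=j + 1).values
    return out
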