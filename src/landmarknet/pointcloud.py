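"""Landmark point clouds in mm and their centred form.

The classifier never sees image intensities: its only input is the
ordered set of the seven landmark positions in real-world millimetre
coordinates, centred on the cloud mean m = (1/7) sum_j l_j so that the
representation — L_j = l_j - m — is invariant to where the heart sits in
the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import VoxelGeometry, voxel_to_mm
from .io import N_LANDMARKS

__all__ = [
    "PointCloud",
    "CenteredPointCloud",
    "to_point_cloud",
    "center_point_cloud",
    "augment_point_clouds",
    "clouds_to_features",
    "clouds_to_frame",
    "frame_to_clouds",
]


@dataclass
class PointCloud:
    """Seven landmark positions in mm, ordered by landmark id 1..7."""

    points: np.ndarray
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 3):
            raise ValueError(
                f"point cloud must be ({N_LANDMARKS}, 3), got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud coordinates must be finite")


@dataclass
class CenteredPointCloud:
    """Landmark positions relative to the cloud centre (mean removed)."""

    points: np.ndarray
    centre: np.ndarray
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.centre = np.asarray(self.centre, dtype=float)
        if self.points.shape != (N_LANDMARKS, 3):
            raise ValueError(
                f"centred cloud must be ({N_LANDMARKS}, 3), got {self.points.shape}"
            )
        if np.any(np.abs(self.points.mean(axis=0)) > 1e-9):
            raise ValueError("centred cloud mean must be zero (within 1e-9 mm)")


def to_point_cloud(
    landmarks, geometry: VoxelGeometry, subject_id: str = "", label: str | None = None
) -> PointCloud:
    """Map (7, 3) landmark voxel indices to mm positions."""
    landmarks = np.asarray(landmarks, dtype=float)
    if landmarks.shape != (N_LANDMARKS, 3):
        raise ValueError(f"expected ({N_LANDMARKS}, 3) landmarks, got {landmarks.shape}")
    return PointCloud(
        points=voxel_to_mm(geometry, landmarks), subject_id=subject_id, label=label
    )


def center_point_cloud(pc: PointCloud) -> CenteredPointCloud:
    centre = pc.points.mean(axis=0)
    return CenteredPointCloud(
        points=pc.points - centre,
        centre=centre,
        subject_id=pc.subject_id,
        label=pc.label,
    )


def augment_point_clouds(
    clouds: list[CenteredPointCloud],
    n_copies: int = 400,
    shift_range_mm: float = 10.0,
    rng: np.random.Generator | None = None,
) -> list:
    """Original clouds plus ``n_copies`` jittered replicas each.

    Each replica shifts every landmark coordinate independently by a
    uniform draw from [-shift_range_mm, +shift_range_mm].  The jitter is
    the stated augmentation law, so replicas are *not* re-centred (their
    mean is close to, but not exactly, zero); they are returned as
    :class:`PointCloud` objects living in the centred frame, which the
    classifier consumes coordinate-wise just like centred clouds.
    """
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    out: list = list(clouds)
    for cloud in clouds:
        for c in range(n_copies):
            jitter = rng.uniform(
                -shift_range_mm, shift_range_mm, size=(N_LANDMARKS, 3)
            )
            out.append(
                PointCloud(
                    points=cloud.points + jitter,
                    subject_id=f"{cloud.subject_id}#aug{c}",
                    label=cloud.label,
                )
            )
    return out


def clouds_to_features(clouds) -> np.ndarray:
    """Stack centred clouds into an (n, 21) landmark-major feature matrix
    (L1z, L1y, L1x, L2z, ... L7x)."""
    return np.stack([c.points.reshape(-1) for c in clouds])


def clouds_to_frame(clouds) -> pd.DataFrame:
    """Long-format table (subject_id, label, landmark_id, z_mm, y_mm, x_mm)."""
    rows = []
    for c in clouds:
        for j in range(N_LANDMARKS):
            rows.append(
                {
                    "subject_id": c.subject_id,
                    "label": c.label,
                    "landmark_id": j + 1,
                    "z_mm": c.points[j, 0],
                    "y_mm": c.points[j, 1],
                    "x_mm": c.points[j, 2],
                }
            )
    return pd.DataFrame(rows)


def frame_to_clouds(frame: pd.DataFrame, centred: bool = True):
    """Inverse of :func:`clouds_to_frame`."""
    clouds = []
    for subject_id, group in frame.groupby("subject_id", sort=False):
        group = group.sort_values("landmark_id")
        points = group[["z_mm", "y_mm", "x_mm"]].to_numpy()
        label = group["label"].iloc[0]
        label = None if pd.isna(label) else label
        if centred:
            centre = points.mean(axis=0)
            clouds.append(
                CenteredPointCloud(points - centre, centre, str(subject_id), label)
            )
        else:
            clouds.append(PointCloud(points, str(subject_id), label))
    return clouds
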