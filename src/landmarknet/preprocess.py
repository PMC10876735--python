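"""Fixed preprocessing to the canonical 33x256x256 stack.

Acquired axial cine stacks vary in slice count (17-54) and acquisition
matrix (132x192 to 192x256).  Every stack is brought to a canonical
33x256x256 grid: slices beyond 33 are discarded (the cropped region lies
beyond the diaphragm), stacks with fewer than 33 slices are padded with
zero-valued slices, and each slice is resampled in-plane to 256x256 with
the two in-plane spacings rescaled independently.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import VoxelGeometry
from .io import AnnotationSet, ImageStack

__all__ = ["CANONICAL_SHAPE", "preprocess_stack", "preprocess_annotations"]

#: (slices, rows, columns) of the canonical network input.
CANONICAL_SHAPE = (33, 256, 256)


def preprocess_stack(
    stack: ImageStack, target_shape: tuple[int, int, int] = CANONICAL_SHAPE
) -> ImageStack:
    """Crop/pad to the target slice count and resample slices in-plane.

    Slices are counted from the top of the stack; slices beyond the
    target count are dropped and missing slices are appended as zeros.
    In-plane resampling is bilinear per slice (anisotropic when the
    input matrix is non-square) and the in-plane spacings are rescaled
    by the inverse of the zoom factors so mm positions are preserved.
    """
    n_slices, n_rows, n_cols = target_shape
    if min(target_shape) <= 0:
        raise ValueError("target shape must be positive")
    values = np.asarray(stack.values, dtype=np.float32)

    # crop or zero-pad along z
    if values.shape[0] >= n_slices:
        values = values[:n_slices]
    else:
        pad = np.zeros((n_slices - values.shape[0],) + values.shape[1:], np.float32)
        values = np.concatenate([values, pad], axis=0)

    zoom_y = n_rows / values.shape[1]
    zoom_x = n_cols / values.shape[2]
    if values.shape[1:] != (n_rows, n_cols):
        values = ndimage.zoom(values, (1.0, zoom_y, zoom_x), order=1, grid_mode=True,
                              mode="grid-constant", prefilter=False)
        values = values.astype(np.float32, copy=False)

    # Voxel-centre convention: output voxel i sits at input index
    # (i + 0.5)/zoom - 0.5, so the origin shifts by -(spacing'*(zoom-1)/2)
    # in-plane and mm positions are preserved exactly.
    sy, sx = stack.geometry.in_plane_spacing
    oz, oy, ox = stack.geometry.origin
    geom = VoxelGeometry(
        in_plane_spacing=(sy / zoom_y, sx / zoom_x),
        slice_spacing=stack.geometry.slice_spacing,
        origin=(
            oz,
            oy - (sy / zoom_y) * (zoom_y - 1) / 2.0,
            ox - (sx / zoom_x) * (zoom_x - 1) / 2.0,
        ),
    )
    return ImageStack(values=values, geometry=geom, subject_id=stack.subject_id)


def preprocess_annotations(
    ann: AnnotationSet,
    original_shape: tuple[int, int, int],
    target_shape: tuple[int, int, int] = CANONICAL_SHAPE,
) -> AnnotationSet:
    """Map annotation voxel indices onto the preprocessed grid.

    Slice indices are unchanged (annotations beyond the cropped slice
    range are rejected — they would refer to discarded anatomy); in-plane
    indices are scaled by the resampling zoom factors.
    """
    n_slices, n_rows, n_cols = target_shape
    if np.any(ann.landmarks[:, 0] > n_slices - 1):
        raise ValueError(
            f"annotation for subject {ann.subject_id!r} has a landmark beyond "
            f"slice {n_slices}; it would be discarded by cropping"
        )
    zoom_y = n_rows / original_shape[1]
    zoom_x = n_cols / original_shape[2]
    # same voxel-centre convention as the image resampling
    landmarks = ann.landmarks * np.array([1.0, zoom_y, zoom_x]) + np.array(
        [0.0, (zoom_y - 1) / 2.0, (zoom_x - 1) / 2.0]
    )
    return AnnotationSet(
        subject_id=ann.subject_id,
        landmarks=landmarks,
        label=ann.label,
        observer_id=ann.observer_id,
    )
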