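"""Image-stack and annotation I/O.

Stacks are read from DICOM series (one file per slice), NIfTI-1 volumes,
or the package's internal ``.npz`` format.  Annotations — seven landmark
voxel positions per subject plus a class label and observer identity —
travel in a small versioned JSON schema (the clinical workstation export
format used to create such annotations is not reimplemented here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .geometry import VoxelGeometry

__all__ = [
    "LANDMARK_NAMES",
    "N_LANDMARKS",
    "LABELS",
    "ImageStack",
    "AnnotationSet",
    "FormatError",
    "MetadataError",
    "SchemaError",
    "read_stack",
    "write_stack",
    "read_annotations",
    "write_annotations",
]

#: Anatomical names of the seven landmarks, indexed by landmark id 1..7.
LANDMARK_NAMES = {
    1: "origin of the left common carotid artery",
    2: "aortic isthmus",
    3: "tricuspid valve",
    4: "aortic valve / neo-aortic valve",
    5: "mitral valve",
    6: "right ventricular apex",
    7: "descending aorta at diaphragm level",
}

N_LANDMARKS = 7

#: Valid class labels; HLHS is the positive class.
LABELS = ("HLHS", "control")

ANNOTATION_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """File could not be parsed in the named format."""


class MetadataError(ValueError):
    """Required geometry metadata (pixel/slice spacing) is missing."""


class SchemaError(ValueError):
    """Annotation JSON does not conform to the documented schema."""


@dataclass
class ImageStack:
    """3D intensity grid indexed (slice, row, column) with voxel geometry."""

    values: np.ndarray
    geometry: VoxelGeometry
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("image stack must be 3D (slice, row, column)")
        if self.values.shape[0] < 1:
            raise ValueError("image stack must contain at least one slice")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class AnnotationSet:
    """Seven landmark voxel positions for one subject.

    ``landmarks`` is an (7, 3) array of (slice, row, column) indices in
    the fixed landmark order 1..7; ``label`` is the class label and
    ``observer_id`` identifies who placed the landmarks.
    """

    subject_id: str
    landmarks: np.ndarray
    label: str
    observer_id: str = "ground_truth"

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.shape != (N_LANDMARKS, 3):
            raise SchemaError(
                f"expected {N_LANDMARKS} landmark positions, got shape "
                f"{self.landmarks.shape}"
            )
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError("landmark positions must be finite")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.observer_id not in ("observer1", "observer2", "ground_truth"):
            raise ValueError(f"unknown observer_id {self.observer_id!r}")

    def validate_bounds(self, shape: tuple[int, int, int]) -> None:
        """Raise if any landmark lies outside a stack of the given shape."""
        upper = np.asarray(shape, dtype=float)
        if np.any(self.landmarks < 0) or np.any(self.landmarks > upper - 1):
            raise ValueError(
                f"landmark position outside stack bounds {shape} "
                f"for subject {self.subject_id!r}"
            )


# ---------------------------------------------------------------------------
# stack I/O


def read_stack(path, format: str = "nifti") -> ImageStack:
    """Read an image stack from disk.

    Parameters
    ----------
    path : path-like
        File (NIfTI, internal ``.npz``) or directory (DICOM series).
    format : {"nifti", "dicom_series", "internal"}
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    if format == "internal":
        return _read_internal(path)
    raise ValueError(f"unknown stack format {format!r}")


def _read_nifti(path: Path) -> ImageStack:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"could not parse {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise MetadataError(f"non-positive voxel spacing in {path}")
    # NIfTI data are (x, y, z); reorder to (z, y, x).
    values = np.transpose(data, (2, 1, 0))
    sx, sy, sz = (float(z) for z in zooms)
    geom = VoxelGeometry(in_plane_spacing=(sy, sx), slice_spacing=sz)
    return ImageStack(values=values, geometry=geom, subject_id=path.stem)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a NIfTI-1 volume (used for phantoms and heatmaps)."""
    import nibabel as nib

    sz, sy, sx = stack.geometry.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    data = np.transpose(np.asarray(stack.values, dtype=np.float32), (2, 1, 0))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def _read_dicom_series(path: Path) -> ImageStack:
    import pydicom

    if not path.is_dir():
        raise FormatError(f"DICOM series path must be a directory: {path}")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"no DICOM slices found in {path}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(str(f)))
        except Exception as exc:
            raise FormatError(f"could not parse {f} as DICOM: {exc}") from exc
    def sort_key(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return int(getattr(ds, "InstanceNumber", 0))
    slices.sort(key=sort_key)
    first = slices[0]
    if not hasattr(first, "PixelSpacing"):
        raise MetadataError("DICOM series lacks PixelSpacing")
    sy, sx = (float(v) for v in first.PixelSpacing)
    if hasattr(first, "SpacingBetweenSlices"):
        sz = float(first.SpacingBetweenSlices)
    elif hasattr(first, "SliceThickness"):
        sz = float(first.SliceThickness)
    else:
        raise MetadataError("DICOM series lacks slice spacing metadata")
    values = np.stack([ds.pixel_array.astype(np.float32) for ds in slices])
    geom = VoxelGeometry(in_plane_spacing=(sy, sx), slice_spacing=sz)
    return ImageStack(values=values, geometry=geom, subject_id=path.name)


def _read_internal(path: Path) -> ImageStack:
    try:
        with np.load(path) as npz:
            values = npz["values"]
            spacing = npz["spacing"]
            origin = npz["origin"]
            subject_id = str(npz["subject_id"])
    except Exception as exc:
        raise FormatError(f"could not parse {path} as internal stack: {exc}") from exc
    geom = VoxelGeometry(
        in_plane_spacing=(float(spacing[1]), float(spacing[2])),
        slice_spacing=float(spacing[0]),
        origin=tuple(float(v) for v in origin),
    )
    return ImageStack(values=values, geometry=geom, subject_id=subject_id)


def write_internal(stack: ImageStack, path) -> None:
    np.savez(
        path,
        values=np.asarray(stack.values, dtype=np.float32),
        spacing=stack.geometry.spacing,
        origin=np.asarray(stack.geometry.origin, dtype=float),
        subject_id=stack.subject_id,
    )


# ---------------------------------------------------------------------------
# annotation I/O


def _annotation_to_dict(ann: AnnotationSet) -> dict:
    return {
        "subject_id": ann.subject_id,
        "label": ann.label,
        "observer_id": ann.observer_id,
        "landmarks": [
            {
                "id": j + 1,
                "name": LANDMARK_NAMES[j + 1],
                "slice": float(ann.landmarks[j, 0]),
                "row": float(ann.landmarks[j, 1]),
                "col": float(ann.landmarks[j, 2]),
            }
            for j in range(N_LANDMARKS)
        ],
    }


def _annotation_from_dict(d: dict) -> AnnotationSet:
    try:
        entries = d["landmarks"]
        subject_id = d["subject_id"]
        label = d["label"]
        observer_id = d.get("observer_id", "ground_truth")
    except KeyError as exc:
        raise SchemaError(f"annotation record missing field {exc}") from exc
    if len(entries) != N_LANDMARKS:
        raise SchemaError(
            f"expected {N_LANDMARKS} landmarks, got {len(entries)} "
            f"for subject {subject_id!r}"
        )
    ids = [e.get("id") for e in entries]
    if sorted(ids) != list(range(1, N_LANDMARKS + 1)):
        raise SchemaError(f"landmark ids must be 1..{N_LANDMARKS}, got {ids}")
    ordered = sorted(entries, key=lambda e: e["id"])
    landmarks = np.array(
        [[e["slice"], e["row"], e["col"]] for e in ordered], dtype=float
    )
    return AnnotationSet(
        subject_id=subject_id,
        landmarks=landmarks,
        label=label,
        observer_id=observer_id,
    )


def write_annotations(annotations: Iterable[AnnotationSet], path) -> None:
    payload = {
        "schema_version": ANNOTATION_SCHEMA_VERSION,
        "annotations": [_annotation_to_dict(a) for a in annotations],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path) -> list[AnnotationSet]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"could not parse {path} as JSON: {exc}") from exc
    if "annotations" not in payload:
        raise SchemaError(f"{path} is not an annotation file (no 'annotations' key)")
    return [_annotation_from_dict(d) for d in payload["annotations"]]
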