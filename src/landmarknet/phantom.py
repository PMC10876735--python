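"""Synthetic two-class phantom cohorts.

Each phantom subject is an axial image stack containing seven bright
Gaussian blobs — one per landmark, with a distinct amplitude per
landmark so appearance as well as location identifies them — plus a
dimmer tubular structure threading landmarks 1-2-7 (vessel-like
context) on a noisy background.  Landmark positions are drawn from
class-conditional spatial distributions: a control template and a
patient template that shifts the aortic-valve landmark substantially
(and landmarks 3 and 6 mildly), with independent isotropic Gaussian
within-class jitter.  A simulated second observer re-annotates the
ground truth with additional jitter.

All randomness derives from the single spec seed through per-subject
spawned seed sequences, so any subject can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import VoxelGeometry, mm_to_voxel, voxel_to_mm
from .io import AnnotationSet, ImageStack, N_LANDMARKS, write_annotations, write_stack

__all__ = ["PhantomSpec", "sample_cohort", "simulate_second_observer", "export_cohort"]


def _default_templates_full():
    # control-class landmark template in mm (z, y, x) for the
    # 33x256x256 grid at 1.75 mm in-plane / 6 mm slices (FOV ~448 mm)
    control = np.array(
        [
            [24.0, 210.0, 230.0],   # 1 left common carotid origin
            [42.0, 215.0, 240.0],   # 2 aortic isthmus
            [102.0, 230.0, 190.0],  # 3 tricuspid valve
            [96.0, 225.0, 225.0],   # 4 aortic valve
            [102.0, 235.0, 260.0],  # 5 mitral valve
            [132.0, 250.0, 210.0],  # 6 right ventricular apex
            [174.0, 260.0, 235.0],  # 7 descending aorta at diaphragm
        ]
    )
    return control


#: between-class template shift in mm per landmark id (patient = control + shift);
#: the aortic-valve landmark carries the dominant shift, landmarks 3 and 6 mild ones
DEFAULT_CLASS_SHIFT = {4: (0.0, 0.0, 40.0), 3: (0.0, 0.0, 10.0), 6: (0.0, 6.0, 8.0)}


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of a two-class phantom cohort."""

    n_patients: int = 46
    n_controls: int = 33
    shape: tuple[int, int, int] = (33, 256, 256)
    in_plane_spacing: tuple[float, float] = (1.75, 1.75)
    slice_spacing: float = 6.0
    control_template_mm: tuple = tuple(map(tuple, _default_templates_full()))
    class_shift_mm: tuple = tuple(sorted(DEFAULT_CLASS_SHIFT.items()))
    jitter_sd_mm: float = 3.0
    render_radius_mm: float = 10.0
    blob_amplitudes: tuple = (500.0, 600.0, 700.0, 800.0, 900.0, 1000.0, 1100.0)
    tube_amplitude: float = 300.0
    tube_radius_mm: float = 4.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd_mm < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise SDs must be non-negative")
        if self.render_radius_mm <= 0:
            raise ValueError("render radius must be positive")
        geom = self.geometry
        upper = voxel_to_mm(geom, np.asarray(self.shape, dtype=float) - 1)
        for label in ("control", "HLHS"):
            for p in self.templates(label):
                if np.any(p < self.render_radius_mm) or np.any(
                    p > upper - self.render_radius_mm
                ):
                    raise ValueError(
                        f"{label} template landmark {tuple(p)} closer than the "
                        f"render radius to the volume boundary"
                    )

    @property
    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry(
            in_plane_spacing=self.in_plane_spacing, slice_spacing=self.slice_spacing
        )

    def templates(self, label: str) -> np.ndarray:
        base = np.asarray(self.control_template_mm, dtype=float)
        if label == "control":
            return base
        shifted = base.copy()
        for lid, shift in self.class_shift_mm:
            shifted[lid - 1] += np.asarray(shift, dtype=float)
        return shifted

    def spec_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def reduced(cls, **overrides) -> "PhantomSpec":
        """Desk-scale spec: 33x64x64 at 3 mm in-plane (FOV 192 mm)."""
        control = (
            (24.0, 90.0, 100.0),
            (42.0, 92.0, 104.0),
            (102.0, 100.0, 80.0),
            (96.0, 96.0, 96.0),
            (102.0, 102.0, 115.0),
            (132.0, 110.0, 90.0),
            (174.0, 115.0, 100.0),
        )
        defaults = dict(
            shape=(33, 64, 64),
            in_plane_spacing=(3.0, 3.0),
            slice_spacing=6.0,
            control_template_mm=control,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _gaussian_patch(shape, geom, centre_mm, sigma_mm):
    """Local +-3 sigma window around centre_mm: returns (slices, patch)."""
    spacing = geom.spacing
    centre_vox = mm_to_voxel(geom, centre_mm)
    half = np.ceil(3.0 * sigma_mm / spacing).astype(int)
    lo = np.maximum(np.floor(centre_vox - half).astype(int), 0)
    hi = np.minimum(np.ceil(centre_vox + half).astype(int) + 1, np.asarray(shape))
    if np.any(lo >= hi):
        return None, None
    axes = [
        (np.arange(lo[d], hi[d]) * spacing[d] + geom.origin[d] - centre_mm[d]) ** 2
        for d in range(3)
    ]
    d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    patch = np.exp(-d2 / (2.0 * sigma_mm ** 2)).astype(np.float32)
    slices = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    return slices, patch


def _render_blob(values, geom, centre_mm, amplitude, sigma_mm):
    """Add a Gaussian blob at centre_mm within a +-3 sigma window."""
    slices, patch = _gaussian_patch(values.shape, geom, centre_mm, sigma_mm)
    if slices is not None:
        values[slices] += amplitude * patch


def _render_tube(values, geom, waypoints_mm, amplitude, radius_mm):
    """Max-composited tube along the polyline through ``waypoints_mm``.

    Max composition keeps the tube's peak intensity at ``amplitude``
    regardless of the sampling density along the line.
    """
    tube = np.zeros_like(values)
    sigma = radius_mm / 2.0
    for a, b in zip(waypoints_mm[:-1], waypoints_mm[1:]):
        length = np.linalg.norm(b - a)
        n_steps = max(int(length / (sigma / 2.0)), 2)
        for t in np.linspace(0.0, 1.0, n_steps):
            slices, patch = _gaussian_patch(values.shape, geom,
                                            a + t * (b - a), sigma)
            if slices is not None:
                np.maximum(tube[slices], amplitude * patch, out=tube[slices])
    values += tube


def sample_subject(spec: PhantomSpec, label: str, subject_id: str, rng):
    """Render one phantom subject; returns (ImageStack, AnnotationSet)."""
    geom = spec.geometry
    template = spec.templates(label)
    upper = voxel_to_mm(geom, np.asarray(spec.shape, dtype=float) - 1)
    margin = spec.render_radius_mm / 2.0

    positions = np.empty_like(template)
    for j in range(N_LANDMARKS):
        for _attempt in range(100):
            candidate = template[j] + rng.normal(0.0, spec.jitter_sd_mm, size=3)
            if np.all(candidate >= margin) and np.all(candidate <= upper - margin):
                positions[j] = candidate
                break
        else:
            raise RuntimeError(
                f"landmark {j + 1} escaped the volume after 100 jitter draws"
            )

    values = np.zeros(spec.shape, dtype=np.float32)
    sigma_blob = spec.render_radius_mm / 2.0
    for j in range(N_LANDMARKS):
        _render_blob(values, geom, positions[j], spec.blob_amplitudes[j], sigma_blob)
    _render_tube(
        values,
        geom,
        positions[[0, 1, 6]],
        spec.tube_amplitude,
        spec.tube_radius_mm,
    )
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)

    landmarks_vox = np.rint(mm_to_voxel(geom, positions))
    landmarks_vox = np.clip(landmarks_vox, 0, np.asarray(spec.shape) - 1)
    stack = ImageStack(values=values, geometry=geom, subject_id=subject_id)
    ann = AnnotationSet(
        subject_id=subject_id,
        landmarks=landmarks_vox,
        label=label,
        observer_id="ground_truth",
    )
    return stack, ann


def sample_cohort(spec: PhantomSpec):
    """Generate the full cohort: list of (ImageStack, AnnotationSet, label)."""
    n_total = spec.n_patients + spec.n_controls
    seeds = np.random.SeedSequence(spec.seed).spawn(n_total)
    cohort = []
    for i in range(n_total):
        label = "HLHS" if i < spec.n_patients else "control"
        prefix = "pat" if label == "HLHS" else "ctl"
        idx = i if label == "HLHS" else i - spec.n_patients
        subject_id = f"{prefix}{idx:03d}"
        rng = np.random.default_rng(seeds[i])
        stack, ann = sample_subject(spec, label, subject_id, rng)
        cohort.append((stack, ann, label))
    return cohort


def simulate_second_observer(
    annotations, geometry: VoxelGeometry, jitter_sd_mm: float, seed: int = 0
):
    """Second-observer annotations: ground truth plus per-coordinate
    Gaussian offsets in mm, re-quantised to voxels."""
    if jitter_sd_mm < 0:
        raise ValueError("jitter SD must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for ann in annotations:
        mm = voxel_to_mm(geometry, ann.landmarks)
        mm = mm + rng.normal(0.0, jitter_sd_mm, size=mm.shape)
        vox = np.rint(mm_to_voxel(geometry, mm))
        out.append(
            AnnotationSet(
                subject_id=ann.subject_id,
                landmarks=vox,
                label=ann.label,
                observer_id="observer2",
            )
        )
    return out


def export_cohort(cohort, directory, spec: PhantomSpec | None = None):
    """Write NIfTI volumes, an annotation JSON and a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    annotations = []
    for stack, ann, label in cohort:
        # clip voxel annotations into bounds before validation on read
        ann.validate_bounds(stack.values.shape)
        write_stack(stack, directory / f"{stack.subject_id}.nii.gz")
        annotations.append(ann)
        rows.append(
            {
                "subject_id": stack.subject_id,
                "label": label,
                "seed": spec.seed if spec is not None else "",
                "spec_hash": spec.spec_hash() if spec is not None else "",
            }
        )
    write_annotations(annotations, directory / "annotations.json")
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return directory
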