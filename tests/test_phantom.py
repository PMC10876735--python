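"""Phantom cohort generation: determinism, learnability, separability."""

import dataclasses

import numpy as np
import pytest

from landmarknet.geometry import mm_to_voxel, voxel_to_mm
from landmarknet.io import read_annotations, read_stack
from landmarknet.phantom import (
    PhantomSpec,
    export_cohort,
    sample_cohort,
    simulate_second_observer,
)
from conftest import tiny_spec


class TestSampleCohort:
    def test_deterministic_for_fixed_seed(self):
        spec = tiny_spec(seed=42)
        c1 = sample_cohort(spec)
        c2 = sample_cohort(spec)
        for (s1, a1, l1), (s2, a2, l2) in zip(c1, c2):
            assert np.array_equal(s1.values, s2.values)
            assert np.array_equal(a1.landmarks, a2.landmarks)
            assert l1 == l2

    def test_different_seed_differs(self):
        c1 = sample_cohort(tiny_spec(seed=1))
        c2 = sample_cohort(tiny_spec(seed=2))
        assert not np.array_equal(c1[0][0].values, c2[0][0].values)

    def test_cohort_sizes_and_labels(self):
        cohort = sample_cohort(tiny_spec(n_patients=4, n_controls=3))
        labels = [l for _, _, l in cohort]
        assert labels.count("HLHS") == 4
        assert labels.count("control") == 3

    def test_zero_jitter_reproduces_template(self):
        spec = tiny_spec(jitter_sd_mm=0.0, noise_sd=0.0)
        cohort = sample_cohort(spec)
        for stack, ann, label in cohort:
            template_vox = np.rint(
                mm_to_voxel(spec.geometry, spec.templates(label))
            )
            assert np.array_equal(ann.landmarks, template_vox)

    def test_brightest_voxel_near_each_landmark(self):
        """Low-noise phantoms must be learnable: the intensity peak within
        a render-radius ball lies within one voxel of the landmark.  Uses
        the realistic reduced geometry, where landmark spacing exceeds the
        render radius."""
        spec = PhantomSpec.reduced(
            n_patients=2, n_controls=2, noise_sd=1.0, jitter_sd_mm=2.0, seed=3
        )
        for stack, ann, _ in sample_cohort(spec):
            spacing = stack.geometry.spacing
            half = np.ceil(spec.render_radius_mm / spacing).astype(int)
            for p in ann.landmarks.astype(int):
                lo = np.maximum(p - half, 0)
                hi = np.minimum(p + half + 1, stack.values.shape)
                window = stack.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                peak = np.unravel_index(window.argmax(), window.shape) + lo
                assert np.all(np.abs(peak - p) <= 1)

    def test_class_shift_applied_to_patient_template(self):
        spec = tiny_spec()
        control = spec.templates("control")
        patient = spec.templates("HLHS")
        # aortic-valve landmark (id 4) carries the dominant shift
        assert np.linalg.norm(patient[3] - control[3]) == pytest.approx(40.0)
        assert np.array_equal(patient[0], control[0])

    def test_template_too_close_to_boundary_rejected(self):
        bad = tuple(
            (2.0, 40.0, 60.0) if i == 0 else t
            for i, t in enumerate(tiny_spec().control_template_mm)
        )
        with pytest.raises(ValueError):
            tiny_spec(control_template_mm=bad)

    def test_ground_truth_clouds_linearly_separable(self, tiny_cohort):
        """Class shift >= 5x jitter SD guarantees separable centred clouds."""
        from landmarknet.classify import classify_many, fit_classifier
        from landmarknet.pointcloud import center_point_cloud, to_point_cloud

        clouds = [
            center_point_cloud(
                to_point_cloud(ann.landmarks, stack.geometry, ann.subject_id, l)
            )
            for stack, ann, l in tiny_cohort
        ]
        model = fit_classifier(clouds)
        predicted = classify_many(model, clouds)
        truth = np.array([l for _, _, l in tiny_cohort])
        assert np.mean(predicted == truth) == 1.0


class TestSecondObserver:
    def test_zero_jitter_is_identity(self, tiny_cohort, tiny_phantom_spec):
        anns = [a for _, a, _ in tiny_cohort]
        obs2 = simulate_second_observer(anns, tiny_phantom_spec.geometry, 0.0)
        for a, b in zip(anns, obs2):
            assert np.array_equal(a.landmarks, b.landmarks)
            assert b.observer_id == "observer2"

    def test_offset_magnitude_matches_chi_mean(self, tiny_phantom_spec):
        from scipy.special import gamma

        from landmarknet.io import AnnotationSet

        sd = 5.0
        geom = tiny_phantom_spec.geometry
        anns = [
            AnnotationSet(f"s{i}", np.full((7, 3), 4.0), label="control")
            for i in range(2000)
        ]
        obs2 = simulate_second_observer(anns, geom, sd, seed=0)
        offsets = np.concatenate(
            [
                voxel_to_mm(geom, b.landmarks) - voxel_to_mm(geom, a.landmarks)
                for a, b in zip(anns, obs2)
            ]
        )
        mags = np.linalg.norm(offsets, axis=1)
        chi3 = np.sqrt(2) * gamma(2.0) / gamma(1.5)
        # voxel re-quantisation adds variance; allow a coarse band
        assert mags.mean() == pytest.approx(sd * chi3, rel=0.35)

    def test_offsets_independent_across_landmarks(self, tiny_phantom_spec):
        from landmarknet.io import AnnotationSet

        geom = tiny_phantom_spec.geometry
        anns = [
            AnnotationSet(f"s{i}", np.full((7, 3), 4.0), label="control")
            for i in range(5000)
        ]
        obs2 = simulate_second_observer(anns, geom, 8.0, seed=1)
        deltas = np.stack([b.landmarks - a.landmarks for a, b in zip(anns, obs2)])
        corr = np.corrcoef(deltas[:, 0, 2], deltas[:, 1, 2])[0, 1]
        assert abs(corr) < 0.05

    def test_negative_sd_rejected(self, tiny_cohort, tiny_phantom_spec):
        with pytest.raises(ValueError):
            simulate_second_observer([], tiny_phantom_spec.geometry, -1.0)


class TestExport:
    def test_round_trip(self, tmp_path, tiny_cohort, tiny_phantom_spec):
        out = export_cohort(tiny_cohort, tmp_path / "cohort", tiny_phantom_spec)
        anns = read_annotations(out / "annotations.json")
        assert len(anns) == len(tiny_cohort)
        for (stack, ann, label), back in zip(tiny_cohort, anns):
            assert back.subject_id == ann.subject_id
            assert np.array_equal(back.landmarks, ann.landmarks)
            stack_back = read_stack(out / f"{ann.subject_id}.nii.gz")
            assert np.allclose(stack_back.values, stack.values, atol=1e-5)

    def test_manifest_rows(self, tmp_path, tiny_cohort, tiny_phantom_spec):
        import pandas as pd

        out = export_cohort(tiny_cohort, tmp_path / "cohort", tiny_phantom_spec)
        manifest = pd.read_csv(out / "manifest.csv")
        assert len(manifest) == len(tiny_cohort)
        assert set(manifest["label"]) == {"HLHS", "control"}

    def test_spec_hash_sensitive_to_fields(self, tiny_phantom_spec):
        other = dataclasses.replace(tiny_phantom_spec, jitter_sd_mm=4.0)
        assert tiny_phantom_spec.spec_hash() != other.spec_hash()
        same = dataclasses.replace(tiny_phantom_spec)
        assert tiny_phantom_spec.spec_hash() == same.spec_hash()
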