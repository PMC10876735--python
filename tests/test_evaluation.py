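"""Displacement metrics, Bland-Altman agreement, stratified CV."""

import numpy as np
import pytest
from scipy.special import gamma

from landmarknet.evaluation import (
    bland_altman,
    bland_altman_table,
    classification_accuracy,
    cohort_landmark_stats,
    displacement,
    run_crossval,
    stratified_kfold,
)


CHI3_MEAN = np.sqrt(2) * gamma(2.0) / gamma(1.5)  # E||N(0, I_3)|| ~ 1.5958


class TestDisplacement:
    def test_three_four_five(self):
        assert displacement((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_zero_for_identical(self):
        assert displacement((1.5, 2.5, 3.5), (1.5, 2.5, 3.5)) == 0.0

    def test_matches_component_oracle(self, rng):
        for _ in range(100):
            g = rng.normal(size=3)
            l = rng.normal(size=3)
            oracle = np.sqrt(sum((gi - li) ** 2 for gi, li in zip(g, l)))
            assert displacement(g, l) == pytest.approx(oracle, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            displacement((0, 0, 0), (1, 2))


class TestCohortLandmarkStats:
    def _positions(self, rng, n):
        return {f"s{i}": rng.uniform(0, 100, size=(7, 3)) for i in range(n)}

    def test_identical_predictions_give_zero(self, rng):
        ann = self._positions(rng, 5)
        report = cohort_landmark_stats(ann, ann)
        assert np.allclose(report["mean_displacement_mm"], 0.0)
        assert np.allclose(report["sd_displacement_mm"], 0.0)

    def test_forced_mean_of_two_subjects(self, rng):
        ann = {s: np.zeros((7, 3)) for s in ("a", "b")}
        pred = {
            "a": np.tile([3.0, 0.0, 0.0], (7, 1)),
            "b": np.tile([5.0, 0.0, 0.0], (7, 1)),
        }
        report = cohort_landmark_stats(pred, ann)
        assert np.allclose(report["mean_displacement_mm"], 4.0)

    def test_interobserver_matches_chi_expectation(self, rng):
        """Gaussian observer-2 jitter of SD sigma has mean 3D offset
        sigma * E||N(0,I_3)||."""
        sigma = 5.0
        n = 3000
        ann = {f"s{i}": np.zeros((7, 3)) for i in range(n)}
        obs2 = {
            s: rng.normal(0, sigma, size=(7, 3)) for s in ann
        }
        report = cohort_landmark_stats(ann, ann, second_observer=obs2)
        expected = sigma * CHI3_MEAN
        assert np.allclose(report["interobserver_mm"], expected, rtol=0.05)

    def test_subject_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cohort_landmark_stats(self._positions(rng, 3), self._positions(rng, 4))

    def test_ratio_present_only_with_second_observer(self, rng):
        ann = self._positions(rng, 4)
        assert "ratio" not in cohort_landmark_stats(ann, ann)
        report = cohort_landmark_stats(ann, ann, second_observer=ann)
        assert "ratio" in report  # NaN here since interobserver is 0
        assert report["ratio"].isna().all()


class TestBlandAltman:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(a, a)
        assert res["bias"] == 0.0 and res["sd"] == 0.0 and res["slope"] == 0.0

    def test_constant_offset(self):
        b = np.array([1.0, 2.0, 3.0])
        res = bland_altman(b + 2.0, b)
        assert res["bias"] == pytest.approx(2.0)
        assert res["sd"] == pytest.approx(0.0)
        assert res["upper_limit"] == pytest.approx(2.0)

    def test_limits_use_196_sd(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        res = bland_altman(a, b)
        assert res["upper_limit"] - res["bias"] == pytest.approx(1.96 * res["sd"])

    def test_recovers_planted_proportional_bias(self, rng):
        n = 500
        b = rng.uniform(50, 150, size=n)
        a = b + 0.1 * (a_mean := (b + b) / 2) / 1 + rng.normal(0, 1.0, size=n)
        # a - b = 0.1 * mean + noise
        res = bland_altman(a, b)
        assert res["slope"] == pytest.approx(0.1, rel=0.2)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])

    def test_table_covers_all_landmarks_and_components(self, rng):
        pred = {f"s{i}": rng.normal(size=(7, 3)) for i in range(5)}
        ann = {s: rng.normal(size=(7, 3)) for s in pred}
        table = bland_altman_table(pred, ann)
        assert len(table) == 21
        assert set(table["component"]) == {"z", "y", "x"}


class TestAccuracy:
    def test_all_correct(self):
        assert classification_accuracy(["a", "b"], ["a", "b"]) == 1.0

    def test_seventy_eight_of_seventy_nine(self):
        truth = ["HLHS"] * 46 + ["control"] * 33
        pred = list(truth)
        pred[0] = "control"
        assert classification_accuracy(truth, pred) == pytest.approx(78 / 79)

    def test_half_correct(self):
        assert classification_accuracy([0, 0, 1, 1], [0, 1, 1, 0]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_accuracy([], [])

    def test_relabelling_invariance(self, rng):
        truth = rng.integers(0, 2, size=50)
        pred = rng.integers(0, 2, size=50)
        acc1 = classification_accuracy(truth, pred)
        acc2 = classification_accuracy(1 - truth, 1 - pred)
        assert acc1 == acc2


class TestStratifiedKFold:
    def test_cohort_partition_46_33(self):
        sids = [f"s{i}" for i in range(79)]
        labels = ["HLHS"] * 46 + ["control"] * 33
        fa = stratified_kfold(sids, labels, k=5, seed=0)
        val_sizes = sorted(len(f["validation"]) for f in fa.folds)
        assert all(v in (15, 16) for v in val_sizes)
        assert sorted(fa.validation_subjects()) == sorted(sids)
        label_of = dict(zip(sids, labels))
        for fold in fa.folds:
            n_pos = sum(label_of[s] == "HLHS" for s in fold["validation"])
            assert n_pos in (9, 10)  # 46/5 = 9.2 within one subject
            assert len(fold["train"]) in (63, 64)

    def test_seed_reproducibility(self):
        sids = [f"s{i}" for i in range(20)]
        labels = ["HLHS"] * 10 + ["control"] * 10
        fa1 = stratified_kfold(sids, labels, k=5, seed=3)
        fa2 = stratified_kfold(sids, labels, k=5, seed=3)
        assert fa1.folds == fa2.folds
        fa3 = stratified_kfold(sids, labels, k=5, seed=4)
        assert fa1.folds != fa3.folds

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(["a", "b", "c"], ["x", "x", "y"], k=2)


class TestRunCrossval:
    def test_annotation_pathway_on_separable_phantoms(self, tiny_cohort):
        result = run_crossval(tiny_cohort, k=3, seed=0, from_annotations=True)
        assert result["accuracy"] == 1.0
        assert len(result["fold_accuracies"]) == 3
        assert len(result["weights"]) == 7
        val = result["fold_assignment"].validation_subjects()
        assert sorted(val) == sorted(a.subject_id for _, a, _ in tiny_cohort)

    def test_svm_augmentation_keeps_separable_accuracy(self, tiny_cohort):
        result = run_crossval(
            tiny_cohort, k=3, seed=0, from_annotations=True, svm_augment=True
        )
        assert result["accuracy"] == 1.0

    def test_network_pathway_report_shape(self, tiny_cohort):
        """Full per-fold train/predict orchestration on a tiny cohort:
        the report carries 7 landmark rows, one accuracy per fold, and
        validation predictions for every subject."""
        from landmarknet.model import ModelConfig, TrainConfig

        result = run_crossval(
            tiny_cohort,
            k=3,
            seed=0,
            model_config=ModelConfig(
                first_layer_filters=3, head_split_depth=2, max_depth=3,
                input_shape=(8, 16, 16), final_pool=2,
            ),
            train_config=TrainConfig(learning_rate=1e-3, epochs=1, seed=0),
        )
        assert len(result["fold_accuracies"]) == 3
        assert len(result["landmark_report"]) == 7
        assert set(result["landmark_report"].columns) >= {
            "mean_displacement_mm", "sd_displacement_mm", "mean_dx_mm",
        }
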