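"""Network architecture contracts, training loop, and image augmentation."""

import numpy as np
import pytest

from landmarknet.geometry import VoxelGeometry
from landmarknet.heatmap import HeatmapConfig, annotation_to_heatmaps
from landmarknet.io import AnnotationSet, ImageStack
from landmarknet.model import (
    AugmentationConfig,
    LandmarkOutOfViewError,
    ModelConfig,
    TrainConfig,
    augment_pair,
    build_model,
    mse_loss,
    predict_heatmaps,
    train_model,
)

# tiny architecture for fast unit tests: 4 slices, 16x16 in-plane
TINY = ModelConfig(
    first_layer_filters=3,
    head_split_depth=2,
    max_depth=3,
    input_shape=(4, 16, 16),
    final_pool=2,
)


class TestModelConfig:
    def test_search_range_boundaries(self):
        ModelConfig(first_layer_filters=3)
        ModelConfig(first_layer_filters=9)
        with pytest.raises(ValueError):
            ModelConfig(first_layer_filters=10)
        with pytest.raises(ValueError):
            ModelConfig(first_layer_filters=2)
        with pytest.raises(ValueError):
            ModelConfig(head_split_depth=7)

    def test_split_must_be_shallower_than_max_depth(self):
        with pytest.raises(ValueError):
            ModelConfig(head_split_depth=3, max_depth=3, input_shape=(4, 16, 16))

    def test_encoder_filter_progression(self):
        net = build_model(ModelConfig())
        assert net.filters == [6, 10, 14, 18, 22, 26, 30]

    def test_output_shape_property(self):
        assert ModelConfig().output_shape == (33, 64, 64)
        assert TINY.output_shape == (4, 8, 8)


class TestArchitecture:
    def test_tiny_model_emits_seven_heads(self, rng):
        net = build_model(TINY, seed=0)
        outs = net.forward(rng.normal(size=(4, 16, 16)).astype(np.float32),
                           train=False)
        assert len(outs) == 7
        assert all(o.shape == (4, 8, 8) for o in outs)

    def test_wrong_input_shape_rejected(self, rng):
        net = build_model(TINY, seed=0)
        with pytest.raises(ValueError):
            net.forward(rng.normal(size=(4, 8, 8)))

    def test_indivisible_inplane_size_rejected(self):
        with pytest.raises(ValueError):
            build_model(
                ModelConfig(input_shape=(4, 18, 18), max_depth=3,
                            head_split_depth=2, final_pool=2)
            )

    def test_parameter_count_increases_with_first_layer_filters(self):
        counts = [
            build_model(
                ModelConfig(first_layer_filters=f, head_split_depth=2,
                            max_depth=3, input_shape=(4, 16, 16), final_pool=2)
            ).n_parameters()
            for f in (3, 5, 7, 9)
        ]
        assert counts == sorted(counts) and len(set(counts)) == 4

    def test_parameter_count_increases_with_head_split_depth(self):
        counts = [
            build_model(
                ModelConfig(head_split_depth=s, max_depth=6,
                            input_shape=(4, 32, 32), final_pool=2)
            ).n_parameters()
            for s in (2, 3, 4)
        ]
        assert counts == sorted(counts) and len(set(counts)) == 3

    def test_save_load_round_trip(self, rng, tmp_path):
        from landmarknet.nn import MultiHeadUNet

        net = build_model(TINY, seed=3)
        x = rng.normal(size=(4, 16, 16)).astype(np.float32)
        outs = net.forward(x, train=False)
        net.save(tmp_path / "ckpt.npz")
        back = MultiHeadUNet.load(tmp_path / "ckpt.npz")
        outs2 = back.forward(x, train=False)
        for a, b in zip(outs, outs2):
            assert np.array_equal(a, b)


def _tiny_training_set(rng, n=4):
    geom = VoxelGeometry(in_plane_spacing=(4.0, 4.0), slice_spacing=8.0)
    pairs = []
    for i in range(n):
        landmarks = np.column_stack(
            [
                rng.integers(1, 3, size=7),
                rng.integers(2, 14, size=7),
                rng.integers(2, 14, size=7),
            ]
        ).astype(float)
        volume = rng.normal(0, 1, size=(4, 16, 16)).astype(np.float32)
        for j, p in enumerate(landmarks.astype(int)):
            volume[p[0], p[1], p[2]] += 50.0 + 20.0 * j
        targets = annotation_to_heatmaps(landmarks, (4, 8, 8), factor=2)
        pairs.append((volume, targets))
    return pairs


class TestTraining:
    def test_loss_decreases_on_separable_signal(self, rng):
        pairs = _tiny_training_set(rng, n=4)
        net = build_model(TINY, seed=0)
        net, history = train_model(
            net, pairs, TrainConfig(learning_rate=1e-2, epochs=5, seed=0)
        )
        assert len(history) == 5
        assert history[-1] < history[0]

    def test_zero_epochs_is_noop(self, rng):
        pairs = _tiny_training_set(rng, n=2)
        net = build_model(TINY, seed=0)
        w_before = net.conv_in.w.copy()
        net, history = train_model(net, pairs, TrainConfig(epochs=0))
        assert history == []
        assert np.array_equal(net.conv_in.w, w_before)

    def test_seeded_training_is_reproducible(self, rng):
        pairs = _tiny_training_set(rng, n=2)
        histories = []
        for _ in range(2):
            net = build_model(TINY, seed=5)
            _, h = train_model(
                net, pairs, TrainConfig(learning_rate=1e-3, epochs=2, seed=9)
            )
            histories.append(h)
        assert histories[0] == histories[1]

    def test_shape_mismatch_rejected_before_training(self, rng):
        net = build_model(TINY, seed=0)
        bad = [(rng.normal(size=(4, 8, 8)), np.zeros((7, 4, 8, 8)))]
        with pytest.raises(ValueError):
            train_model(net, bad, TrainConfig(epochs=1))

    def test_mse_zero_for_perfect_prediction(self, rng):
        targets = [rng.normal(size=(4, 8, 8)).astype(np.float32) for _ in range(7)]
        loss, grads, per_head = mse_loss(targets, targets)
        assert per_head == [0.0] * 7
        assert loss == 0.0
        assert all(np.all(g == 0) for g in grads)

    def test_mse_known_value(self):
        preds = [np.ones((2, 2, 2), np.float32)] * 7
        tgts = [np.zeros((2, 2, 2), np.float32)] * 7
        loss, _, _ = mse_loss(preds, tgts)
        assert loss == pytest.approx(1.0)


class TestPredictHeatmaps:
    def test_output_contract(self, rng):
        net = build_model(TINY, seed=0)
        geom = VoxelGeometry(in_plane_spacing=(4.0, 4.0), slice_spacing=8.0)
        stack = ImageStack(rng.normal(size=(4, 16, 16)).astype(np.float32), geom)
        heatmaps = predict_heatmaps(net, stack)
        assert [h.landmark_id for h in heatmaps] == [1, 2, 3, 4, 5, 6, 7]
        assert all(h.values.shape == (4, 8, 8) for h in heatmaps)
        # coarse geometry: spacing doubled, origin shifted by half a coarse cell
        assert heatmaps[0].grid_geometry.in_plane_spacing == (8.0, 8.0)

    def test_non_canonical_input_rejected(self, rng):
        net = build_model(TINY, seed=0)
        geom = VoxelGeometry()
        stack = ImageStack(rng.normal(size=(4, 8, 8)).astype(np.float32), geom)
        with pytest.raises(ValueError):
            predict_heatmaps(net, stack)


class TestAugmentation:
    def _pair(self, rng):
        geom = VoxelGeometry(in_plane_spacing=(2.0, 2.0), slice_spacing=6.0)
        values = rng.normal(size=(4, 32, 32)).astype(np.float32)
        stack = ImageStack(values, geom)
        ann = AnnotationSet(
            "s",
            np.column_stack(
                [
                    rng.integers(0, 4, size=7),
                    rng.integers(8, 24, size=7),
                    rng.integers(8, 24, size=7),
                ]
            ).astype(float),
            label="control",
        )
        return stack, ann

    def test_zero_limits_are_identity(self, rng):
        stack, ann = self._pair(rng)
        cfg = AugmentationConfig(
            shift_limit=0, rotate_limit=0, scale_limit=0, blur_limit=0,
            distort_limit=0, enabled=True,
        )
        out_stack, out_ann = augment_pair(stack, ann, cfg, rng)
        assert np.allclose(out_stack.values, stack.values, atol=1e-5)
        assert np.allclose(out_ann.landmarks, ann.landmarks, atol=1e-9)

    def test_shift_bounded_by_limit(self, rng):
        stack, ann = self._pair(rng)
        cfg = AugmentationConfig(
            shift_limit=0.02, rotate_limit=0, scale_limit=0, blur_limit=0,
            distort_limit=0, enabled=True,
        )
        for _ in range(20):
            _, out_ann = augment_pair(stack, ann, cfg, rng)
            delta = np.abs(out_ann.landmarks - ann.landmarks)
            assert np.all(delta[:, 0] == 0)  # slices untouched
            assert np.all(delta[:, 1:] <= 0.02 * 32 + 1e-9)

    def test_pure_rotation_preserves_distance_to_centre(self, rng):
        stack, ann = self._pair(rng)
        cfg = AugmentationConfig(
            shift_limit=0, rotate_limit=10, scale_limit=0, blur_limit=0,
            distort_limit=0, enabled=True,
        )
        _, out_ann = augment_pair(stack, ann, cfg, rng)
        centre = np.array([15.5, 15.5])
        r_before = np.linalg.norm(ann.landmarks[:, 1:] - centre, axis=1)
        r_after = np.linalg.norm(out_ann.landmarks[:, 1:] - centre, axis=1)
        assert np.allclose(r_before, r_after, atol=1e-6)

    def test_disabled_config_rejected(self, rng):
        stack, ann = self._pair(rng)
        with pytest.raises(ValueError):
            augment_pair(stack, ann, AugmentationConfig(), rng)

    def test_landmark_leaving_view_flagged(self, rng):
        geom = VoxelGeometry(in_plane_spacing=(2.0, 2.0), slice_spacing=6.0)
        stack = ImageStack(rng.normal(size=(4, 32, 32)).astype(np.float32), geom)
        edge = np.array([[0.0, 0.0, 31.0]] * 7)
        ann = AnnotationSet("s", edge, label="control")
        cfg = AugmentationConfig(
            shift_limit=0.2, rotate_limit=0, scale_limit=0, blur_limit=0,
            distort_limit=0, enabled=True,
        )
        with pytest.raises(LandmarkOutOfViewError):
            for _ in range(50):
                augment_pair(stack, ann, cfg, rng)
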