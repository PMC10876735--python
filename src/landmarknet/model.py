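"""Network configuration, training and prediction.

Wraps the NumPy multi-head U-Net (:mod:`landmarknet.nn`) behind the
pipeline's configuration surface.  The reference protocol trains for 32
epochs with Adam at learning rate 5e-4, batch size 2 and mean-squared
error over the heatmap voxels; the heads share a U-Net-like encoder
backbone and split at a configurable decoder depth.  Image-level
augmentation (shift/rotate/scale/blur/optical distortion) is available
but disabled by default — the final reference model used none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import AnnotationSet, ImageStack, N_LANDMARKS
from .heatmap import HeatmapConfig, HeatmapVolume, annotation_to_heatmaps
from .nn import Adam, MultiHeadUNet

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "AugmentationConfig",
    "build_model",
    "train_model",
    "predict_heatmaps",
    "augment_pair",
    "mse_loss",
    "LandmarkOutOfViewError",
]

FIRST_LAYER_FILTER_RANGE = (3, 9)
HEAD_SPLIT_DEPTH_RANGE = (2, 6)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``first_layer_filters`` (search range 3-9, default 6) sets the
    filter count at full resolution; filters grow by ``filter_increment``
    per downsampling.  ``head_split_depth`` (search range 2-6, default
    3) is the deepest decoder level replicated per head.  ``max_depth``
    counts resolution levels; reduced input shapes may shrink it.
    """

    first_layer_filters: int = 6
    head_split_depth: int = 3
    max_depth: int = 7
    filter_increment: int = 4
    input_shape: tuple[int, int, int] = (33, 256, 256)
    n_heads: int = N_LANDMARKS
    final_pool: int = 4
    #: initialisation of each head's final linear convolution: "he"
    #: (reference protocol) or "zeros" (short-schedule desk runs)
    final_init: str = "he"

    def __post_init__(self) -> None:
        lo, hi = FIRST_LAYER_FILTER_RANGE
        if not lo <= self.first_layer_filters <= hi:
            raise ValueError(
                f"first_layer_filters must be in [{lo}, {hi}], "
                f"got {self.first_layer_filters}"
            )
        lo, hi = HEAD_SPLIT_DEPTH_RANGE
        if not lo <= self.head_split_depth <= hi:
            raise ValueError(
                f"head_split_depth must be in [{lo}, {hi}], "
                f"got {self.head_split_depth}"
            )
        if self.head_split_depth >= self.max_depth:
            raise ValueError("head_split_depth must be smaller than max_depth")

    @property
    def output_shape(self) -> tuple[int, int, int]:
        d, h, w = self.input_shape
        return (d, h // self.final_pool, w // self.final_pool)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol (reference defaults).

    ``beta1``/``beta2`` are the Adam moment decays; shorter schedules
    benefit from a faster-adapting second moment (smaller beta2).
    """

    learning_rate: float = 5e-4
    batch_size: int = 2
    epochs: int = 32
    beta1: float = 0.9
    beta2: float = 0.999
    warmup_steps: int = 0
    #: learning rate decays linearly after warmup to this fraction of
    #: ``learning_rate`` by the last step (1.0 = constant)
    final_lr_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("Adam betas must lie in [0, 1)")
        if self.warmup_steps < 0:
            raise ValueError("warmup_steps must be >= 0")
        if not 0 < self.final_lr_fraction <= 1:
            raise ValueError("final_lr_fraction must be in (0, 1]")


@dataclass(frozen=True)
class AugmentationConfig:
    """Image-level augmentation limits.

    Shift is a fraction of the image size, rotation in degrees, scale a
    relative factor, blur a kernel half-width in pixels, distortion a
    radial warp amplitude; ``apply_probability`` is the chance a
    transformed copy is produced at all.
    """

    shift_limit: float = 0.02
    rotate_limit: float = 4.0
    scale_limit: float = 0.15
    blur_limit: float = 4.0
    distort_limit: float = 3.0
    apply_probability: float = 1.0
    enabled: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.apply_probability <= 1.0:
            raise ValueError("apply_probability must be in [0, 1]")


class LandmarkOutOfViewError(ValueError):
    """A transformed landmark left the field of view; skip the pair."""


def build_model(config: ModelConfig, seed: int = 0) -> MultiHeadUNet:
    return MultiHeadUNet(
        input_shape=config.input_shape,
        first_layer_filters=config.first_layer_filters,
        max_depth=config.max_depth,
        split_depth=config.head_split_depth,
        n_heads=config.n_heads,
        filter_increment=config.filter_increment,
        final_pool=config.final_pool,
        final_init=config.final_init,
        seed=seed,
    )


def mse_loss(predictions, targets):
    """Mean of per-head MSE and its gradient w.r.t. the predictions.

    Also returns the per-head MSE components (the total is their mean)
    so training can monitor each head's convergence separately.
    """
    n_heads = len(predictions)
    per_head = []
    grads = []
    for pred, tgt in zip(predictions, targets):
        diff = np.asarray(pred, dtype=np.float32) - np.asarray(tgt, dtype=np.float32)
        per_head.append(float(np.mean(diff ** 2)))
        grads.append(2.0 * diff / (diff.size * n_heads))
    return sum(per_head) / n_heads, grads, per_head


class LossHistory(list):
    """Per-epoch mean losses; ``per_head[j]`` holds head j's own curve."""

    def __init__(self, *args):
        super().__init__(*args)
        self.per_head: list[list[float]] = []


def train_model(model: MultiHeadUNet, training_set, config: TrainConfig):
    """Train on (stack values, per-head target heatmaps) pairs.

    ``training_set`` is a sequence of ``(volume, targets)`` with volume
    of the model's input shape and targets of shape (n_heads,) + output
    shape.  Returns the model and the per-epoch mean loss history (a
    list whose ``per_head`` attribute carries each head's curve).
    """
    out_shape = model.output_shape
    for volume, targets in training_set:
        if tuple(np.shape(volume)) != model.input_shape:
            raise ValueError(
                f"stack shape {np.shape(volume)} does not match model input "
                f"{model.input_shape}"
            )
        if tuple(np.shape(targets)) != (model.n_heads,) + out_shape:
            raise ValueError(
                f"target shape {np.shape(targets)} does not match "
                f"{(model.n_heads,) + out_shape}"
            )
    rng = np.random.default_rng(config.seed)
    opt = Adam(model, lr=config.learning_rate, beta1=config.beta1,
               beta2=config.beta2)
    history = LossHistory()
    n = len(training_set)
    steps_per_epoch = (n + config.batch_size - 1) // config.batch_size
    total_steps = config.epochs * steps_per_epoch
    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_heads = np.zeros(model.n_heads)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            model.zero_grad()
            for idx in batch:
                volume, targets = training_set[idx]
                preds = model.forward(np.asarray(volume, dtype=np.float32))
                loss, grads, per_head = mse_loss(preds, targets)
                model.backward([g / len(batch) for g in grads])
                epoch_loss += loss
                epoch_heads += per_head
            step += 1
            if config.warmup_steps and step <= config.warmup_steps:
                # linear warmup guards the ReLUs against the large initial
                # residual (a cold start at full step size can silence whole
                # decoder heads for the rest of a short schedule)
                opt.lr = config.learning_rate * step / config.warmup_steps
            elif config.final_lr_fraction < 1.0:
                span = max(total_steps - config.warmup_steps, 1)
                progress = min((step - config.warmup_steps) / span, 1.0)
                opt.lr = config.learning_rate * (
                    1.0 - (1.0 - config.final_lr_fraction) * progress
                )
            else:
                opt.lr = config.learning_rate
            opt.step()
        history.append(epoch_loss / n)
        history.per_head.append(list(epoch_heads / n))
    return model, history


def predict_heatmaps(model: MultiHeadUNet, stack: ImageStack) -> list[HeatmapVolume]:
    """Predict the seven heatmap volumes for a preprocessed stack."""
    if tuple(stack.values.shape) != model.input_shape:
        raise ValueError(
            f"stack shape {stack.values.shape} does not match model input "
            f"{model.input_shape}; preprocess first"
        )
    outputs = model.forward(stack.values, train=False)
    from .geometry import VoxelGeometry

    sy, sx = stack.geometry.in_plane_spacing
    oz, oy, ox = stack.geometry.origin
    p = model.final_pool
    coarse_geom = VoxelGeometry(
        in_plane_spacing=(sy * p, sx * p),
        slice_spacing=stack.geometry.slice_spacing,
        origin=(oz, oy + sy * (p - 1) / 2.0, ox + sx * (p - 1) / 2.0),
    )
    return [
        HeatmapVolume(values=out, landmark_id=j + 1, grid_geometry=coarse_geom)
        for j, out in enumerate(outputs)
    ]


def build_training_set(
    stacks,
    annotations,
    model_config: ModelConfig,
    heatmap_config: HeatmapConfig = HeatmapConfig(),
):
    """Pair preprocessed stacks with target heatmaps on the head grid."""
    out_shape = model_config.output_shape
    pairs = []
    for stack, ann in zip(stacks, annotations):
        targets = annotation_to_heatmaps(
            ann.landmarks, out_shape, factor=model_config.final_pool,
            config=heatmap_config,
        )
        pairs.append((stack.values, targets))
    return pairs


# ---------------------------------------------------------------------------
# image-level augmentation


def augment_pair(
    stack: ImageStack,
    annotation: AnnotationSet,
    config: AugmentationConfig,
    rng: np.random.Generator,
):
    """Random in-plane shift/rotation/scale plus blur and distortion.

    One in-plane similarity transform is drawn per call and applied to
    every slice and to the annotation's in-plane coordinates; blur and
    optical distortion perturb intensities only.  With all limits zero
    the pair is returned unchanged.  Raises
    :class:`LandmarkOutOfViewError` if a transformed landmark leaves the
    field of view.
    """
    if not config.enabled:
        raise ValueError("augmentation is disabled in this configuration")
    if rng.uniform() > config.apply_probability:
        return stack, annotation

    values = np.asarray(stack.values, dtype=np.float32)
    n_rows, n_cols = values.shape[1:]
    shift = rng.uniform(-config.shift_limit, config.shift_limit, size=2) * np.array(
        [n_rows, n_cols]
    )
    angle = np.deg2rad(rng.uniform(-config.rotate_limit, config.rotate_limit))
    scale = 1.0 + rng.uniform(-config.scale_limit, config.scale_limit)

    centre = np.array([(n_rows - 1) / 2.0, (n_cols - 1) / 2.0])
    rot = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    fwd = scale * rot  # output = fwd @ (input - centre) + centre + shift

    # scipy's affine_transform maps output -> input coordinates
    inv = np.linalg.inv(fwd)
    offset = centre - inv @ (centre + shift)
    out = np.empty_like(values)
    for z in range(values.shape[0]):
        out[z] = ndimage.affine_transform(
            values[z], inv, offset=offset, order=1, mode="constant", cval=0.0
        )

    if config.blur_limit > 0:
        sigma = rng.uniform(0.0, config.blur_limit / 2.0)
        if sigma > 1e-6:
            for z in range(out.shape[0]):
                out[z] = ndimage.gaussian_filter(out[z], sigma)

    if config.distort_limit > 0:
        out = _optical_distortion(out, config.distort_limit, rng)

    landmarks = annotation.landmarks.copy()
    inplane = landmarks[:, 1:]
    inplane = (fwd @ (inplane - centre).T).T + centre + shift
    landmarks[:, 1:] = inplane
    if (
        np.any(landmarks[:, 1] < 0)
        or np.any(landmarks[:, 1] > n_rows - 1)
        or np.any(landmarks[:, 2] < 0)
        or np.any(landmarks[:, 2] > n_cols - 1)
    ):
        raise LandmarkOutOfViewError(
            f"augmented landmark left the field of view for "
            f"subject {annotation.subject_id!r}"
        )

    aug_stack = ImageStack(values=out, geometry=stack.geometry,
                           subject_id=stack.subject_id)
    aug_ann = AnnotationSet(
        subject_id=annotation.subject_id,
        landmarks=landmarks,
        label=annotation.label,
        observer_id=annotation.observer_id,
    )
    return aug_stack, aug_ann


def _optical_distortion(values, limit, rng):
    """Mild radial (barrel/pincushion) warp of the slice plane."""
    strength = rng.uniform(-limit, limit) * 0.01
    n_rows, n_cols = values.shape[1:]
    cy, cx = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    ry, rx = (yy - cy) / n_rows, (xx - cx) / n_cols
    r2 = ry ** 2 + rx ** 2
    factor = 1.0 + strength * r2
    coords = np.array([cy + (yy - cy) * factor, cx + (xx - cx) * factor])
    out = np.empty_like(values)
    for z in range(values.shape[0]):
        out[z] = ndimage.map_coordinates(values[z], coords, order=1, mode="constant")
    return out


def augment_training_pairs(pairs, config: AugmentationConfig, rng):
    """Double the training set: originals plus one modified copy each.

    Pairs whose transformed landmarks leave the field of view contribute
    only their original.
    """
    out = list(pairs)
    for stack, ann in pairs:
        try:
            out.append(augment_pair(stack, ann, config, rng))
        except LandmarkOutOfViewError:
            continue
    return out
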