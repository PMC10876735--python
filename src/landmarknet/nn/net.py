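"""Multi-head 3D U-Net for heatmap regression, in NumPy.

The network is an encoder-decoder with a shared 3D-convolutional
backbone and seven segmentation heads, one per anatomical landmark.
Depth ``d`` indexes resolution levels: the in-plane resolution is halved
per level (z is never resampled) and the number of filters grows
additively by ``filter_increment`` per level.  Downsampling uses strided
3x3x3 convolution (stride 1x2x2), upsampling the corresponding
transpose convolution; a non-strided convolution sits between
consecutive resampling steps and skip connexions concatenate
equal-resolution encoder features into the decoder.  Decoder steps
landing at depths <= ``split_depth`` are replicated per head; deeper
steps are shared.  Each head finishes with in-plane max pooling by
``final_pool`` and a linear 3x3x3 convolution to a single channel.

Hidden activations are ReLU; weights are He-initialised.  Gradients are
exact (hand-derived, finite-difference-checked in the tests), and the
whole apparatus is deterministic given the initialisation seed.
"""

from __future__ import annotations

import numpy as np

from . import ops

__all__ = ["Conv3D", "ConvTranspose3D", "MultiHeadUNet", "Adam"]


#: initial bias for hidden (ReLU) convolutions; a small positive value
#: keeps every unit initially active, which matters on short schedules
#: where a region of dead units cannot be revived in time
HIDDEN_BIAS_INIT = 0.05


class Conv3D:
    """3x3x3 convolution, 'same' padding, optional stride and ReLU."""

    def __init__(self, cin, cout, rng, stride=(1, 1, 1), activation="relu"):
        scale = np.sqrt(2.0 / (27 * cin))
        self.w = rng.normal(0.0, scale, size=(27, cin, cout)).astype(np.float32)
        bias0 = HIDDEN_BIAS_INIT if activation == "relu" else 0.0
        self.b = np.full(cout, bias0, dtype=np.float32)
        self.stride = stride
        self.activation = activation
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None
        self._pre = None

    def forward(self, x, train=True):
        y = ops.conv3d_forward(x, self.w, self.b, self.stride)
        if train:
            self._x = x
            self._pre = y if self.activation == "relu" else None
        if self.activation == "relu":
            y = ops.relu(y)
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = ops.relu_backward(dy, self._pre)
        dw, db = ops.conv3d_backward_weights(self._x, dy, self.stride)
        self.dw += dw
        self.db += db
        return ops.conv3d_backward_input(dy, self.w, self._x.shape[:3], self.stride)

    def parameters(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def n_parameters(self):
        return self.w.size + self.b.size


class ConvTranspose3D:
    """Transpose 3x3x3 convolution (adjoint of the strided convolution)."""

    def __init__(self, cin, cout, rng, stride=(1, 2, 2), activation="relu"):
        scale = np.sqrt(2.0 / (27 * cin))
        self.w = rng.normal(0.0, scale, size=(27, cout, cin)).astype(np.float32)
        bias0 = HIDDEN_BIAS_INIT if activation == "relu" else 0.0
        self.b = np.full(cout, bias0, dtype=np.float32)
        self.stride = stride
        self.activation = activation
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None
        self._pre = None

    def forward(self, x, train=True):
        y = ops.conv3d_transpose_forward(x, self.w, self.b, self.stride)
        if train:
            self._x = x
            self._pre = y if self.activation == "relu" else None
        if self.activation == "relu":
            y = ops.relu(y)
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = ops.relu_backward(dy, self._pre)
        dw, db = ops.conv3d_transpose_backward_weights(self._x, dy, self.stride)
        self.dw += dw
        self.db += db
        return ops.conv3d_transpose_backward_input(
            dy, self.w, self.stride, self._x.shape[:3]
        )

    def parameters(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def n_parameters(self):
        return self.w.size + self.b.size


class MultiHeadUNet:
    def __init__(
        self,
        input_shape=(33, 256, 256),
        first_layer_filters: int = 6,
        max_depth: int = 7,
        split_depth: int = 3,
        n_heads: int = 7,
        filter_increment: int = 4,
        final_pool: int = 4,
        final_init: str = "he",
        seed: int = 0,
    ):
        if input_shape[1] % 2 ** (max_depth - 1) or input_shape[2] % 2 ** (max_depth - 1):
            raise ValueError(
                f"in-plane size {input_shape[1:]} not divisible by "
                f"2^{max_depth - 1} for max_depth={max_depth}"
            )
        rng = np.random.default_rng(seed)
        self.input_shape = tuple(input_shape)
        self.max_depth = max_depth
        self.split_depth = split_depth
        self.n_heads = n_heads
        self.final_pool = final_pool
        f = [first_layer_filters + filter_increment * d for d in range(max_depth)]
        self.filters = f

        self.conv_in = Conv3D(1, f[0], rng)
        self.down = [Conv3D(f[d - 1], f[d], rng, stride=(1, 2, 2))
                     for d in range(1, max_depth)]
        self.mid = [Conv3D(f[d], f[d], rng) for d in range(1, max_depth)]

        # decoder steps landing at depth d, d = max_depth-2 .. 0
        self.shared_up, self.shared_merge = {}, {}
        self.head_up = [dict() for _ in range(n_heads)]
        self.head_merge = [dict() for _ in range(n_heads)]
        for d in range(max_depth - 2, -1, -1):
            if d > split_depth:
                self.shared_up[d] = ConvTranspose3D(f[d + 1], f[d], rng)
                self.shared_merge[d] = Conv3D(2 * f[d], f[d], rng)
            else:
                for h in range(n_heads):
                    self.head_up[h][d] = ConvTranspose3D(f[d + 1], f[d], rng)
                    self.head_merge[h][d] = Conv3D(2 * f[d], f[d], rng)
        if final_init not in ("he", "zeros"):
            raise ValueError("final_init must be 'he' or 'zeros'")
        self.final_init = final_init
        self.head_final = [Conv3D(f[0], 1, rng, activation=None)
                           for _ in range(n_heads)]
        if final_init == "zeros":
            # zero output layers start every head at an identical, exactly
            # zero prediction, so the first gradients are the clean
            # feature-growing direction rather than a random transient
            for layer in self.head_final:
                layer.w[...] = 0.0
        self._pool_cache = [None] * n_heads
        self._pool_xshape = [None] * n_heads

    # -- plumbing ---------------------------------------------------------

    def layers(self):
        yield self.conv_in
        yield from self.down
        yield from self.mid
        yield from self.shared_up.values()
        yield from self.shared_merge.values()
        for h in range(self.n_heads):
            yield from self.head_up[h].values()
            yield from self.head_merge[h].values()
            yield self.head_final[h]

    def parameters(self):
        for layer in self.layers():
            yield from layer.parameters()

    def n_parameters(self) -> int:
        return sum(layer.n_parameters() for layer in self.layers())

    def zero_grad(self):
        for layer in self.layers():
            layer.dw[...] = 0.0
            layer.db[...] = 0.0

    @property
    def output_shape(self):
        d, h, w = self.input_shape
        return (d, h // self.final_pool, w // self.final_pool)

    # -- forward / backward ----------------------------------------------

    def forward(self, x, train=True):
        """x: (D, H, W) volume -> list of n_heads (D, H/p, W/p) heatmaps."""
        if tuple(x.shape) != self.input_shape:
            raise ValueError(
                f"expected input of shape {self.input_shape}, got {x.shape}"
            )
        a = np.asarray(x, dtype=np.float32)
        # standardise intensities: scanner scaling is arbitrary, and a
        # zero-mean unit-variance input keeps the initial output (and hence
        # the first optimisation phase) independent of the intensity scale
        a = (a - a.mean()) / (a.std() + 1e-6)
        a = a[..., None]
        skips = []
        a = self.conv_in.forward(a, train)
        skips.append(a)
        for d in range(1, self.max_depth):
            a = self.down[d - 1].forward(a, train)
            a = self.mid[d - 1].forward(a, train)
            skips.append(a)

        b = skips[-1]
        self._shared_concat_c = {}
        for d in range(self.max_depth - 2, self.split_depth, -1):
            b = self.shared_up[d].forward(b, train)
            b = np.concatenate([b, skips[d]], axis=-1)
            b = self.shared_merge[d].forward(b, train)
        self._skips = skips if train else None

        outputs = []
        for h in range(self.n_heads):
            c = b
            for d in range(min(self.split_depth, self.max_depth - 2), -1, -1):
                c = self.head_up[h][d].forward(c, train)
                c = np.concatenate([c, skips[d]], axis=-1)
                c = self.head_merge[h][d].forward(c, train)
            pooled, idx = ops.maxpool_inplane_forward(c, self.final_pool)
            if train:
                self._pool_cache[h] = idx
                self._pool_xshape[h] = c.shape
            out = self.head_final[h].forward(pooled, train)
            outputs.append(out[..., 0])
        return outputs

    def backward(self, d_outputs):
        """Accumulate parameter gradients from per-head output gradients."""
        skips = self._skips
        dskips = [np.zeros_like(s) for s in skips]
        db_total = None
        for h in range(self.n_heads):
            dpool = self.head_final[h].backward(
                np.asarray(d_outputs[h], dtype=np.float32)[..., None]
            )
            dc = ops.maxpool_inplane_backward(
                dpool, self._pool_cache[h], self.final_pool, self._pool_xshape[h]
            )
            for d in range(0, min(self.split_depth, self.max_depth - 2) + 1):
                dcat = self.head_merge[h][d].backward(dc)
                nf = self.filters[d]
                dskips[d] += dcat[..., nf:]
                dc = self.head_up[h][d].backward(dcat[..., :nf])
            db_total = dc if db_total is None else db_total + dc

        db = db_total
        for d in range(self.split_depth + 1, self.max_depth - 1):
            dcat = self.shared_merge[d].backward(db)
            nf = self.filters[d]
            dskips[d] += dcat[..., nf:]
            db = self.shared_up[d].backward(dcat[..., :nf])
        dskips[self.max_depth - 1] += db

        da = dskips[self.max_depth - 1]
        for d in range(self.max_depth - 1, 0, -1):
            da = self.mid[d - 1].backward(da)
            da = self.down[d - 1].backward(da)
            da = da + dskips[d - 1]
        self.conv_in.backward(da)

    def reinit_head(self, h: int, seed: int = 0) -> None:
        """Reinitialise one head's decoder (fresh He draw, final layer per
        ``final_init``).  The shared trunk and the other heads are
        untouched; useful when a single head's initialisation stalls."""
        rng = np.random.default_rng(seed)
        f = self.filters
        for d in sorted(self.head_up[h], reverse=True):
            self.head_up[h][d] = ConvTranspose3D(f[d + 1], f[d], rng)
            self.head_merge[h][d] = Conv3D(2 * f[d], f[d], rng)
        self.head_final[h] = Conv3D(f[0], 1, rng, activation=None)
        if self.final_init == "zeros":
            self.head_final[h].w[...] = 0.0

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers()):
            state[f"w{i}"] = layer.w
            state[f"b{i}"] = layer.b
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers()):
            layer.w[...] = state[f"w{i}"]
            layer.b[...] = state[f"b{i}"]

    def save(self, path) -> None:
        meta = dict(
            input_shape=self.input_shape,
            first_layer_filters=self.filters[0],
            max_depth=self.max_depth,
            split_depth=self.split_depth,
            n_heads=self.n_heads,
            filter_increment=self.filters[1] - self.filters[0]
            if len(self.filters) > 1 else 4,
            final_pool=self.final_pool,
            final_init=self.final_init,
        )
        np.savez(path, __meta__=np.array([repr(meta)]), **self.state_dict())

    @classmethod
    def load(cls, path) -> "MultiHeadUNet":
        import ast

        with np.load(path, allow_pickle=False) as npz:
            meta = ast.literal_eval(str(npz["__meta__"][0]))
            net = cls(**meta)
            net.load_state_dict({k: npz[k] for k in npz.files if k != "__meta__"})
        return net


class Adam:
    """Adam optimizer over a model's (param, grad) pairs."""

    def __init__(self, model, lr=5e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.parameters()]
        self.v = [np.zeros_like(p) for p, _ in model.parameters()]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, (p, g) in enumerate(self.model.parameters()):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p -= self.lr * (self.m[i] / bias1) / (np.sqrt(self.v[i] / bias2) + self.eps)
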