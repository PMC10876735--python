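"""Low-level 3D convolution primitives with hand-derived gradients.

All tensors are channels-last: ``(D, H, W, C)``.  Convolutions use
3x3x3 kernels with zero ('same') padding of one voxel per spatial axis
and stride ``(sz, sy, sx)``; weights are stored as ``(27, C_in, C_out)``
indexed by the flattened kernel offset, so forward and both backward
passes reduce to 27 tall-skinny GEMMs over the flattened spatial grid —
a layout that keeps per-offset temporaries small enough for full-size
(33x256x256) volumes.  Transpose convolution is implemented as the
exact adjoint of the strided convolution, which is what guarantees
shape round-trips (H -> H/2 -> H).

Every gradient here is validated against central finite differences in
the test suite; nothing in this module knows about the network.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "KERNEL_OFFSETS",
    "conv3d_forward",
    "conv3d_backward_input",
    "conv3d_backward_weights",
    "conv3d_transpose_forward",
    "conv3d_transpose_backward_input",
    "conv3d_transpose_backward_weights",
    "maxpool_inplane_forward",
    "maxpool_inplane_backward",
    "relu",
    "relu_backward",
]

#: (dz, dy, dx) offsets of the 3x3x3 kernel, flattened in C order.
KERNEL_OFFSETS = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


def _out_size(n: int, s: int) -> int:
    # 'same' padding of 1 with kernel 3: out = floor((n - 1)/s) + 1
    return (n - 1) // s + 1


def _pad(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))


def _offset_slices(k: int, stride, out_shape):
    dz, dy, dx = KERNEL_OFFSETS[k]
    sz, sy, sx = stride
    do, ho, wo = out_shape
    return (
        slice(dz, dz + sz * (do - 1) + 1, sz),
        slice(dy, dy + sy * (ho - 1) + 1, sy),
        slice(dx, dx + sx * (wo - 1) + 1, sx),
    )


def conv3d_forward(x, weights, bias=None, stride=(1, 1, 1)):
    """x: (D, H, W, Cin); weights: (27, Cin, Cout) -> (Do, Ho, Wo, Cout)."""
    d, h, w, cin = x.shape
    cout = weights.shape[2]
    out_shape = tuple(_out_size(n, s) for n, s in zip((d, h, w), stride))
    n = int(np.prod(out_shape))
    xp = _pad(np.asarray(x, dtype=np.float32))
    y = np.zeros((n, cout), dtype=np.float32)
    for k in range(27):
        xs = xp[_offset_slices(k, stride, out_shape)].reshape(n, cin)
        y += xs @ weights[k]
    if bias is not None:
        y += bias
    return y.reshape(out_shape + (cout,))


def conv3d_backward_input(dy, weights, x_shape, stride=(1, 1, 1)):
    """Gradient of conv3d_forward w.r.t. its input."""
    out_shape = dy.shape[:3]
    n = int(np.prod(out_shape))
    cout = dy.shape[3]
    cin = weights.shape[1]
    dyf = np.ascontiguousarray(dy, dtype=np.float32).reshape(n, cout)
    dxp = np.zeros((x_shape[0] + 2, x_shape[1] + 2, x_shape[2] + 2, cin),
                   dtype=np.float32)
    for k in range(27):
        g = dyf @ weights[k].T
        dxp[_offset_slices(k, stride, out_shape)] += g.reshape(out_shape + (cin,))
    return dxp[1:-1, 1:-1, 1:-1, :]


def conv3d_backward_weights(x, dy, stride=(1, 1, 1)):
    """Gradients of conv3d_forward w.r.t. weights and bias."""
    out_shape = dy.shape[:3]
    n = int(np.prod(out_shape))
    cin = x.shape[3]
    cout = dy.shape[3]
    dyf = np.ascontiguousarray(dy, dtype=np.float32).reshape(n, cout)
    xp = _pad(np.asarray(x, dtype=np.float32))
    dw = np.empty((27, cin, cout), dtype=np.float32)
    for k in range(27):
        xs = xp[_offset_slices(k, stride, out_shape)].reshape(n, cin)
        dw[k] = xs.T @ dyf
    db = dyf.sum(axis=0)
    return dw, db


def conv3d_transpose_forward(x, weights, bias=None, stride=(1, 1, 1),
                             out_spatial=None):
    """Adjoint of the strided convolution: upsamples by ``stride``.

    ``weights`` has shape (27, Cout, Cin) — the layout of the
    downsampling convolution whose adjoint this is.  ``out_spatial``
    defaults to input size times stride per axis.
    """
    in_shape = x.shape[:3]
    cin = x.shape[3]
    cout = weights.shape[1]
    if out_spatial is None:
        out_spatial = tuple(nn * s for nn, s in zip(in_shape, stride))
    n = int(np.prod(in_shape))
    xf = np.ascontiguousarray(x, dtype=np.float32).reshape(n, cin)
    yp = np.zeros((out_spatial[0] + 2, out_spatial[1] + 2, out_spatial[2] + 2, cout),
                  dtype=np.float32)
    for k in range(27):
        g = xf @ weights[k].T
        yp[_offset_slices(k, stride, in_shape)] += g.reshape(in_shape + (cout,))
    y = yp[1:-1, 1:-1, 1:-1, :]
    if bias is not None:
        y = y + bias
    return y


def conv3d_transpose_backward_input(dy, weights, stride=(1, 1, 1), in_spatial=None):
    """Gradient of the transpose convolution w.r.t. its input — a plain
    strided convolution of ``dy`` with the same weights."""
    if in_spatial is None:
        in_spatial = tuple(_out_size(nb, s) for nb, s in zip(dy.shape[:3], stride))
    n = int(np.prod(in_spatial))
    cout = dy.shape[3]
    cin = weights.shape[2]
    dyp = _pad(np.asarray(dy, dtype=np.float32))
    dx = np.zeros((n, cin), dtype=np.float32)
    for k in range(27):
        dys = dyp[_offset_slices(k, stride, in_spatial)].reshape(n, cout)
        dx += dys @ weights[k]
    return dx.reshape(in_spatial + (cin,))


def conv3d_transpose_backward_weights(x, dy, stride=(1, 1, 1)):
    """Gradients of the transpose convolution w.r.t. weights and bias."""
    in_shape = x.shape[:3]
    n = int(np.prod(in_shape))
    cin = x.shape[3]
    cout = dy.shape[3]
    xf = np.ascontiguousarray(x, dtype=np.float32).reshape(n, cin)
    dyp = _pad(np.asarray(dy, dtype=np.float32))
    dw = np.empty((27, cout, cin), dtype=np.float32)
    for k in range(27):
        dys = dyp[_offset_slices(k, stride, in_shape)].reshape(n, cout)
        dw[k] = dys.T @ xf
    db = dy.reshape(-1, cout).sum(axis=0)
    return dw, db


def maxpool_inplane_forward(x, factor: int):
    """In-plane max pooling by ``factor`` (z untouched).  Returns the
    pooled array and the argmax indices needed for the backward pass."""
    if factor == 1:
        return x, None
    d, h, w, c = x.shape
    ho, wo = h // factor, w // factor
    xw = x.reshape(d, ho, factor, wo, factor, c)
    xw = xw.transpose(0, 1, 3, 5, 2, 4).reshape(d, ho, wo, c, factor * factor)
    idx = np.argmax(xw, axis=-1)
    y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
    return y, idx


def maxpool_inplane_backward(dy, idx, factor: int, x_shape):
    if factor == 1:
        return dy
    d, h, w, c = x_shape
    ho, wo = h // factor, w // factor
    dxw = np.zeros((d, ho, wo, c, factor * factor), dtype=np.float32)
    np.put_along_axis(dxw, idx[..., None], dy[..., None], axis=-1)
    dxw = dxw.reshape(d, ho, wo, c, factor, factor).transpose(0, 1, 4, 2, 5, 3)
    return dxw.reshape(d, h, w, c)


def relu(x):
    return np.maximum(x, 0.0)


def relu_backward(dy, x):
    return np.where(x > 0, dy, 0.0).astype(np.float32)
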