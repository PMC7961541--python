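"""Differentiable operations for the segmentation network.

Convolution is computed by im2col + GEMM; its input gradient uses a
cached scatter-index map and ``np.bincount`` (col2im).  Bilinear
resampling is expressed as a pair of per-axis interpolation matrices so
that its adjoint is exact.  Space-to-depth and depth-to-space are pure
reshape/transpose bijections and are exact inverses of each other under
the fixed convention documented on :func:`space_to_depth`.
"""

from __future__ import annotations

import functools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, make_op

__all__ = [
    "add", "relu", "conv2d", "max_pool2d", "batch_norm2d", "linear",
    "global_avg_pool", "bilinear_resize", "space_to_depth", "depth_to_space",
    "concat", "flatten2d", "mul_add", "softmax_cross_entropy", "softmax",
]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# ---------------------------------------------------------------------------
# elementwise / structural
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")
    out = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return make_op(out, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = np.where(mask, x.data, 0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return make_op(out, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return make_op(out, tuple(tensors), backward)


def flatten2d(x: Tensor) -> Tensor:
    """(N, C, 1, 1) or (N, C, H, W) -> (N, C*H*W)."""
    x = _as_tensor(x)
    n = x.shape[0]
    out = x.data.reshape(n, -1)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.shape))

    return make_op(out, (x,), backward)


def mul_add(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Elementwise ``x * w + b`` with broadcasting over the batch axis.

    Used by the class-activation head where each pooled map mean is
    scaled by a scalar class weight.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    out = x.data * w.data + b.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * w.data)
        if w.requires_grad:
            w._accumulate(_unbroadcast(g * x.data, w.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return make_op(out, (x, w, b), backward)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _conv_geometry(h, w, kh, kw, stride, pad, dil):
    eh, ew = dil * (kh - 1) + 1, dil * (kw - 1) + 1
    ho = (h + 2 * pad - eh) // stride + 1
    wo = (w + 2 * pad - ew) // stride + 1
    return eh, ew, ho, wo


def _im2col(x: np.ndarray, kh, kw, stride, pad, dil):
    n, c, h, w = x.shape
    eh, ew, ho, wo = _conv_geometry(h, w, kh, kw, stride, pad, dil)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = sliding_window_view(x, (eh, ew), axis=(2, 3))
    v = v[:, :, ::stride, ::stride, ::dil, ::dil]  # (n, c, ho, wo, kh, kw)
    cols = np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3))
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


@functools.lru_cache(maxsize=128)
def _col2im_index(c, h, w, kh, kw, stride, pad, dil):
    """Flat scatter indices from col layout (c*kh*kw, ho*wo) into the
    padded input image (c, h+2p, w+2p)."""
    _, _, ho, wo = _conv_geometry(h, w, kh, kw, stride, pad, dil)
    hp, wp = h + 2 * pad, w + 2 * pad
    ci, ki, kj = np.indices((c, kh, kw)).reshape(3, -1)
    oh, ow = np.indices((ho, wo)).reshape(2, -1)
    rows = ki[:, None] * dil + oh[None, :] * stride
    cols = kj[:, None] * dil + ow[None, :] * stride
    flat = ci[:, None] * (hp * wp) + rows * wp + cols
    return flat.ravel(), hp, wp


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad, dil):
    n, c, h, w = xshape
    flat, hp, wp = _col2im_index(c, h, w, kh, kw, stride, pad, dil)
    out = np.empty((n, c, h, w), dtype=dcols.dtype)
    size = c * hp * wp
    for i in range(n):
        buf = np.bincount(flat, weights=dcols[i].ravel(), minlength=size)
        img = buf.reshape(c, hp, wp)
        out[i] = img[:, pad:pad + h, pad:pad + w]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, pad: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (Cout, Cin, kh, kw)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: {cin} input channels, weight expects {cin_w}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad, dilation)
    w2 = weight.data.reshape(cout, -1)
    out = np.matmul(w2, cols)  # (n, cout, ho*wo)
    if bias is not None:
        out += bias.data[:, None]
    out = out.reshape(n, cout, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gf = g.reshape(n, cout, -1)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gf.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T, gf)
            x._accumulate(_col2im(dcols, x.shape, kh, kw, stride, pad, dilation))

    return make_op(out, parents, backward)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.shape
    _, _, ho, wo = _conv_geometry(h, w, kernel, kernel, stride, pad, 1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    v = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    v = v[:, :, ::stride, ::stride]                     # (n, c, ho, wo, k, k)
    v = v.reshape(n, c, ho, wo, kernel * kernel)
    arg = v.argmax(axis=-1)
    out = np.take_along_axis(v, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        hp, wp = h + 2 * pad, w + 2 * pad
        oh, ow = np.indices((ho, wo))
        ki, kj = arg // kernel, arg % kernel
        rows = oh * stride + ki            # (n, c, ho, wo)
        cols = ow * stride + kj
        ci = np.arange(c)[None, :, None, None]
        flat = (ci * hp * wp + rows * wp + cols).reshape(n, -1)
        dx = np.empty((n, c, h, w), dtype=g.dtype)
        for i in range(n):
            buf = np.bincount(flat[i], weights=g[i].ravel(),
                              minlength=c * hp * wp)
            dx[i] = buf.reshape(c, hp, wp)[:, pad:pad + h, pad:pad + w]
        x._accumulate(dx)

    return make_op(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C, 1, 1) per-channel spatial mean."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / (h * w), x.shape))

    return make_op(out, (x,), backward)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray, *,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[:, None, None]) * inv[:, None, None]
    out = gamma.data[:, None, None] * xhat + beta.data[:, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = g * gamma.data[:, None, None]
            if training:
                m1 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
                m2 = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = inv[:, None, None] * (dxhat - m1 - xhat * m2)
            else:
                dx = inv[:, None, None] * dxhat
            x._accumulate(dx)

    return make_op(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# linear
# ---------------------------------------------------------------------------

def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """(N, F) @ (O, F).T + (O,)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    out = x.data @ weight.data.T
    if bias is not None:
        out = out + bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=0))
        if weight.requires_grad:
            weight._accumulate(g.T @ x.data)
        if x.requires_grad:
            x._accumulate(g @ weight.data)

    return make_op(out, parents, backward)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=64)
def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Bilinear interpolation matrix (n_out, n_in), half-pixel-center
    convention: source coordinate s = (t + 0.5) * n_in / n_out - 0.5."""
    if n_in == 1:
        return np.ones((n_out, 1))
    t = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    t = np.clip(t, 0.0, n_in - 1.0)
    i0 = np.floor(t).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = t - i0
    m = np.zeros((n_out, n_in))
    rows = np.arange(n_out)
    np.add.at(m, (rows, i0), 1.0 - f)
    np.add.at(m, (rows, i1), f)
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.shape
    a = interp_matrix(h, out_h).astype(x.dtype)
    b = interp_matrix(w, out_w).astype(x.dtype)
    out = np.einsum("oh,nchw,pw->ncop", a, x.data, b, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.einsum("oh,ncop,pw->nchw", a, g, b, optimize=True))

    return make_op(out, (x,), backward)


def _s2d_data(x: np.ndarray, r: int) -> np.ndarray:
    n, c, h, w = x.shape
    y = x.reshape(n, c, h // r, r, w // r, r)
    return np.ascontiguousarray(y.transpose(0, 1, 3, 5, 2, 4)).reshape(
        n, c * r * r, h // r, w // r)


def _d2s_data(x: np.ndarray, r: int) -> np.ndarray:
    n, c, h, w = x.shape
    y = x.reshape(n, c // (r * r), r, r, h, w)
    return np.ascontiguousarray(y.transpose(0, 1, 4, 2, 5, 3)).reshape(
        n, c // (r * r), h * r, w * r)


def space_to_depth(x: Tensor, r: int) -> Tensor:
    """(N, C, H, W) -> (N, C*r^2, H/r, W/r).

    Convention: the r x r offsets of each block are read row-major and
    fill the channel axis fastest, i.e. input channel c and offset
    (i, j) land on output channel ``c*r*r + i*r + j``.
    """
    x = _as_tensor(x)
    n, c, h, w = x.shape
    if h % r or w % r:
        raise ValueError(f"space_to_depth: spatial dims {(h, w)} not divisible by r={r}")
    out = _s2d_data(x.data, r)

    def backward(g):
        if x.requires_grad:
            x._accumulate(_d2s_data(g, r))

    return make_op(out, (x,), backward)


def depth_to_space(x: Tensor, r: int) -> Tensor:
    """(N, C, H, W) -> (N, C/r^2, H*r, W*r); exact inverse of
    :func:`space_to_depth` under the same block-order convention."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    if c % (r * r):
        raise ValueError(f"depth_to_space: {c} channels not divisible by r^2={r * r}")
    out = _d2s_data(x.data, r)

    def backward(g):
        if x.requires_grad:
            x._accumulate(_s2d_data(g, r))

    return make_op(out, (x,), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray, *,
                          reduction: str = "mean") -> Tensor:
    """Cross-entropy of a softmax over the class axis (axis 1).

    ``logits`` is (N, K) or (N, K, H, W); ``labels`` holds integer class
    ids of shape (N,) or (N, H, W).  Stabilised with log-sum-exp.
    ``reduction`` is ``"mean"`` (over every labelled element) or ``"sum"``.
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z - zmax).sum(axis=1, keepdims=True)) + zmax
    true = np.take_along_axis(z, np.expand_dims(labels, 1), axis=1)
    per = (lse - true)[:, 0]
    count = per.size
    if reduction == "mean":
        val = per.mean()
    elif reduction == "sum":
        val = per.sum()
    else:
        raise ValueError(f"unknown reduction {reduction!r}")

    def backward(g):
        if not logits.requires_grad:
            return
        p = softmax(z, axis=1)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, np.expand_dims(labels, 1), 1.0, axis=1)
        scale = g / count if reduction == "mean" else g
        logits._accumulate((p - onehot) * scale)

    return make_op(np.asarray(val), (logits,), backward)
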