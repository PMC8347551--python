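"""Differentiable operations on :class:`~facnet.nn.tensor.Tensor`.

Convolutions are computed by explicit kernel-position slicing (a small
Python loop over the k*k kernel offsets with fully vectorised NumPy slices),
which keeps forward and backward symmetric and supports stride and dilation
without stride-trick gymnastics.  Bilinear resampling is expressed as a
cached ``scipy.sparse`` matrix per (input-size, output-size) pair, so its
backward pass is just the transposed matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .tensor import Tensor, as_tensor


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / structural
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor._from_op(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._from_op(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return Tensor._from_op(out_data, (a, b), backward)


def sum(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:  # noqa: A001
    t = as_tensor(t)
    out_data = t.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not t.requires_grad:
            return
        if axis is None:
            t._accumulate(np.broadcast_to(g, t.data.shape).astype(t.data.dtype))
        else:
            g2 = g if keepdims else np.expand_dims(g, axis)
            t._accumulate(np.broadcast_to(g2, t.data.shape).copy())

    return Tensor._from_op(out_data, (t,), backward)


def mean(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    t = as_tensor(t)
    n = t.data.size if axis is None else np.prod(
        [t.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum(t, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(t: Tensor, shape) -> Tensor:
    t = as_tensor(t)
    out_data = t.data.reshape(shape)

    def backward(g):
        if t.requires_grad:
            t._accumulate(g.reshape(t.data.shape))

    return Tensor._from_op(out_data, (t,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    mask = t.data > 0
    out_data = np.where(mask, t.data, 0)

    def backward(g):
        if t.requires_grad:
            t._accumulate(g * mask)

    return Tensor._from_op(out_data, (t,), backward)


def sigmoid(t: Tensor) -> Tensor:
    t = as_tensor(t)
    # numerically stable logistic
    x = t.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

    def backward(g):
        if t.requires_grad:
            t._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._from_op(out_data, (t,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
            ho: int, wo: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            hi = i * dilation
            wi = j * dilation
            cols[:, :, i, j] = xp[:, :, hi:hi + (ho - 1) * stride + 1:stride,
                                  wi:wi + (wo - 1) * stride + 1:stride]
    return cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation. ``w``: (C_out, C_in, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wid = x.data.shape
    cout, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cin}")
    ke_h = (kh - 1) * dilation + 1
    ke_w = (kw - 1) * dilation + 1
    ho = (h + 2 * padding - ke_h) // stride + 1
    wo = (wid + 2 * padding - ke_w) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"conv2d: kernel {ke_h}x{ke_w} larger than padded input {h}x{wid}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    cols = _im2col(xp, kh, kw, stride, dilation, ho, wo)
    out_data = np.tensordot(cols, w.data, axes=([1, 2, 3], [1, 2, 3]))  # N,Ho,Wo,Cout
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5]))  # Cout,C,kh,kw
            w._accumulate(dw)
        if x.requires_grad:
            dcols = np.tensordot(g, w.data, axes=([1], [0]))  # N,Ho,Wo,C,kh,kw
            dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # N,C,kh,kw,Ho,Wo
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    hi = i * dilation
                    wi = j * dilation
                    dxp[:, :, hi:hi + (ho - 1) * stride + 1:stride,
                        wi:wi + (wo - 1) * stride + 1:stride] += dcols[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor._from_op(out_data, parents, backward)


def deconv2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact x2 upsampling).

    ``w``: (C_in, C_out, 2, 2). Non-overlapping output blocks: each input
    pixel expands into its own 2x2 patch.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wid = x.data.shape
    cin, cout = w.data.shape[:2]
    if cin != c:
        raise ValueError(f"deconv2x2: input has {c} channels, weight expects {cin}")
    y6 = np.einsum("nchw,cdij->ndhiwj", x.data, w.data, optimize=True)
    out_data = np.ascontiguousarray(y6.reshape(n, cout, 2 * h, 2 * wid))
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g6 = g.reshape(n, cout, h, 2, wid, 2)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(np.einsum("nchw,ndhiwj->cdij", x.data, g6, optimize=True))
        if x.requires_grad:
            x._accumulate(np.einsum("ndhiwj,cdij->nchw", g6, w.data, optimize=True))

    return Tensor._from_op(out_data, parents, backward)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping max pooling (stride = kernel), ceil mode: the input is
    padded with -inf up to a multiple of ``kernel``."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    k = int(kernel)
    ho, wo = -(-h // k), -(-w // k)
    ph, pw = ho * k - h, wo * k - w
    xd = x.data
    if ph or pw:
        xd = np.pad(xd, ((0, 0), (0, 0), (0, ph), (0, pw)),
                    constant_values=-np.inf)
    win = xd.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5) \
        .reshape(n, c, ho, wo, k * k)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dxp = dwin.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5) \
            .reshape(n, c, ho * k, wo * k)
        x._accumulate(np.ascontiguousarray(dxp[:, :, :h, :w]))

    return Tensor._from_op(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1) spatial mean."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / (h * w), x.data.shape).copy())

    return Tensor._from_op(out_data, (x,), backward)


def global_max_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C,1,1) spatial maximum of each channel."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1).reshape(n, c, 1, 1)

    def backward(g):
        if x.requires_grad:
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, idx[..., None], g.reshape(n, c, 1), axis=-1)
            x._accumulate(dflat.reshape(x.data.shape))

    return Tensor._from_op(out_data, (x,), backward)


def channel_max(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,1,H,W) across-channel maximum (ties: first channel)."""
    x = as_tensor(x)
    idx = x.data.argmax(axis=1, keepdims=True)
    out_data = np.take_along_axis(x.data, idx, axis=1)

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            np.put_along_axis(dx, idx, g, axis=1)
            x._accumulate(dx)

    return Tensor._from_op(out_data, (x,), backward)


def channel_mean(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,1,H,W) across-channel mean."""
    return mean(x, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

_RESIZE_CACHE: dict[tuple[int, int, int, int], sparse.csr_matrix] = {}


def _bilinear_matrix(hi: int, wi: int, ho: int, wo: int) -> sparse.csr_matrix:
    """Sparse (ho*wo, hi*wi) bilinear interpolation operator
    (half-pixel-centre convention, edges clamped)."""
    key = (hi, wi, ho, wo)
    mat = _RESIZE_CACHE.get(key)
    if mat is not None:
        return mat

    def axis_weights(n_in, n_out):
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        i0 = np.floor(src).astype(int)
        frac = src - i0
        i0c = np.clip(i0, 0, n_in - 1)
        i1c = np.clip(i0 + 1, 0, n_in - 1)
        return i0c, i1c, 1.0 - frac, frac

    y0, y1, wy0, wy1 = axis_weights(hi, ho)
    x0, x1, wx0, wx1 = axis_weights(wi, wo)
    rows, cols, vals = [], [], []
    out_idx = np.arange(ho * wo).reshape(ho, wo)
    for ys, wys in ((y0, wy0), (y1, wy1)):
        for xs, wxs in ((x0, wx0), (x1, wx1)):
            rows.append(out_idx.ravel())
            cols.append((ys[:, None] * wi + xs[None, :]).ravel())
            vals.append((wys[:, None] * wxs[None, :]).ravel())
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ho * wo, hi * wi),
    )
    mat.sum_duplicates()
    _RESIZE_CACHE[key] = mat
    return mat


def bilinear_resize(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Differentiable bilinear resize of (N,C,H,W) to spatial ``size``."""
    x = as_tensor(x)
    n, c, hi, wi = x.data.shape
    ho, wo = size
    if (hi, wi) == (ho, wo):
        return x
    mat = _bilinear_matrix(hi, wi, ho, wo)
    flat = x.data.reshape(n * c, hi * wi)
    out_data = (mat @ flat.T).T.reshape(n, c, ho, wo).astype(x.data.dtype)

    def backward(g):
        if x.requires_grad:
            gflat = g.reshape(n * c, ho * wo)
            x._accumulate((mat.T @ gflat.T).T.reshape(x.data.shape)
                          .astype(x.data.dtype))

    return Tensor._from_op(out_data, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    h, w = x.data.shape[2:]
    return bilinear_resize(x, (2 * h, 2 * w))


# ---------------------------------------------------------------------------
# normalisation / dense
# ---------------------------------------------------------------------------

def spatial_softmax(x: Tensor) -> Tensor:
    """Softmax over the H*W positions of each (N,C) slice, computed in the
    max-shifted form for overflow safety."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    shifted = flat - flat.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=-1, keepdims=True)
    out_data = s.reshape(x.data.shape)

    def backward(g):
        if x.requires_grad:
            gf = g.reshape(n, c, h * w)
            dot = (gf * s).sum(axis=-1, keepdims=True)
            x._accumulate((s * (gf - dot)).reshape(x.data.shape))

    return Tensor._from_op(out_data, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x: (N, C_in), w: (C_out, C_in)."""
    x, w = as_tensor(x), as_tensor(w)
    out_data = x.data @ w.data.T
    if b is not None:
        out_data = out_data + b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if w.requires_grad:
            w._accumulate(g.T @ x.data)
        if x.requires_grad:
            x._accumulate(g @ w.data)

    return Tensor._from_op(out_data, parents, backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation; updates running stats in place when
    training."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)
    m = n * h * w

    def backward(g):
        dbeta = g.sum(axis=(0, 2, 3))
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        if beta.requires_grad:
            beta._accumulate(dbeta)
        if gamma.requires_grad:
            gamma._accumulate(dgamma)
        if x.requires_grad:
            gs = gamma.data.reshape(1, c, 1, 1) * inv_std.reshape(1, c, 1, 1)
            if training:
                dx = gs * (g
                           - dbeta.reshape(1, c, 1, 1) / m
                           - xhat * dgamma.reshape(1, c, 1, 1) / m)
            else:
                dx = gs * g
            x._accumulate(dx)

    return Tensor._from_op(out_data, (x, gamma, beta), backward)
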