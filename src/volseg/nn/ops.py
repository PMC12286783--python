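"""Differentiable operations with hand-derived adjoints.

Conventions: feature maps are ``(H, W, D, C)`` with channels last; token
matrices are ``(N, K)``.  Convolution kernels are stored flattened as
``(k³·C_in, C_out)`` matrices over an im2col expansion, which turns both the
forward and the backward pass into large matrix products.

The Fourier mixing op implements ``y = Re(IFFT(W ⊙ FFT(x)))`` over the
spatial axes per channel.  For real ``x`` the adjoints are exact:
``x̄ = Re(IFFT(conj(W) ⊙ FFT(ḡ)))`` and, writing ``c = IFFT(ḡ) ⊙ FFT(x)``,
``∂L/∂Re(W) = Re(c)``, ``∂L/∂Im(W) = −Im(c)``.  Anti-Hermitian components of
``W`` lie in the kernel of the map (their image is purely imaginary and is
discarded by the real part), so the effective learned filter is Hermitian
and the output is real by construction.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .autodiff import Tensor, accumulate, as_tensor, make_op

__all__ = [
    "add", "sub", "mul", "div", "matmul", "reshape", "transpose", "concat",
    "sum", "mean", "exp", "log", "gelu", "relu", "softmax", "log_softmax",
    "layer_norm", "crop3d", "gather_grid", "spectral_mix", "conv3d",
    "up_conv3d",
]


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        accumulate(a, _unbroadcast(g, a.data.shape))
        accumulate(b, _unbroadcast(g, b.data.shape))

    return make_op(out, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data - b.data

    def backward(g):
        accumulate(a, _unbroadcast(g, a.data.shape))
        accumulate(b, _unbroadcast(-g, b.data.shape))

    return make_op(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return make_op(out, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data

    def backward(g):
        accumulate(a, _unbroadcast(g / b.data, a.data.shape))
        accumulate(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return make_op(out, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        accumulate(a, _unbroadcast(ga, a.data.shape))
        accumulate(b, _unbroadcast(gb, b.data.shape))

    return make_op(out, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = a.data.reshape(shape)

    def backward(g):
        accumulate(a, g.reshape(a.data.shape))

    return make_op(out, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        accumulate(a, np.transpose(g, inv))

    return make_op(out, (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            accumulate(t, piece)

    return make_op(out, tuple(tensors), backward)


def sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            accumulate(a, np.broadcast_to(g, a.data.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        accumulate(a, np.broadcast_to(g, a.data.shape))

    return make_op(out, (a,), backward)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(sum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)

    def backward(g):
        accumulate(a, g * out)

    return make_op(out, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out = np.log(a.data)

    def backward(g):
        accumulate(a, g / a.data)

    return make_op(out, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0.0)

    def backward(g):
        accumulate(a, g * (a.data > 0))

    return make_op(out, (a,), backward)


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a) -> Tensor:
    """Exact Gaussian-error linear unit ``x·Φ(x)``."""
    a = as_tensor(a)
    cdf = 0.5 * (1.0 + special.erf(a.data * _INV_SQRT2))
    out = a.data * cdf

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data * a.data)
        accumulate(a, g * (cdf + a.data * pdf))

    return make_op(out, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        accumulate(a, s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return make_op(s, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse

    def backward(g):
        accumulate(a, g - np.exp(out) * g.sum(axis=axis, keepdims=True))

    return make_op(out, (a,), backward)


def layer_norm(x, gain, bias, eps: float = 1e-6) -> Tensor:
    """Layer normalisation over the last axis with learnable gain/bias."""
    x, gain, bias = as_tensor(x), as_tensor(gain), as_tensor(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gain.data + bias.data

    def backward(g):
        axes = tuple(range(g.ndim - 1))
        accumulate(gain, (g * xhat).sum(axis=axes))
        accumulate(bias, g.sum(axis=axes))
        gx_hat = g * gain.data
        m1 = gx_hat.mean(axis=-1, keepdims=True)
        m2 = (gx_hat * xhat).mean(axis=-1, keepdims=True)
        accumulate(x, inv * (gx_hat - m1 - xhat * m2))

    return make_op(out, (x, gain, bias), backward)


def crop3d(x, slices: tuple[slice, slice, slice]) -> Tensor:
    """Spatial crop of an ``(H, W, D, C)`` map (adjoint zero-pads)."""
    x = as_tensor(x)
    sl = tuple(slices) + (slice(None),)
    out = x.data[sl]

    def backward(g):
        full = np.zeros_like(x.data)
        full[sl] = g
        accumulate(x, full)

    return make_op(out, (x,), backward)


def gather_grid(table, idx_h, idx_w, idx_d) -> Tensor:
    """Resample a per-grid-position parameter table onto another grid.

    ``table`` has shape ``(h, w, d, ...)``; the output is
    ``table[idx_h][:, idx_w][:, :, idx_d]`` (nearest-index resampling per
    axis).  The adjoint scatter-adds duplicate reads back into the table.
    When the index arrays are identities the op is exact and cost-free in
    the backward pass.
    """
    table = as_tensor(table)
    ih = np.asarray(idx_h, dtype=np.intp)
    iw = np.asarray(idx_w, dtype=np.intp)
    idd = np.asarray(idx_d, dtype=np.intp)
    out = table.data[np.ix_(ih, iw, idd)]
    identity = (
        table.data.shape[:3] == (len(ih), len(iw), len(idd))
        and np.array_equal(ih, np.arange(len(ih)))
        and np.array_equal(iw, np.arange(len(iw)))
        and np.array_equal(idd, np.arange(len(idd)))
    )

    def backward(g):
        if identity:
            accumulate(table, g)
            return
        gt = np.zeros_like(table.data)
        np.add.at(gt, np.ix_(ih, iw, idd), g)
        accumulate(table, gt)

    return make_op(out, (table,), backward)


def spectral_mix(x, w_re, w_im, axes: tuple[int, ...] = (0, 1, 2)) -> Tensor:
    """Frequency-domain filtering ``Re(IFFT(W ⊙ FFT(x)))`` per channel.

    ``x`` is real with channels on the last axis; ``w_re``/``w_im`` hold the
    complex filter over the same frequency grid.  With ``W = 1`` the op is
    the identity on real input.
    """
    x, w_re, w_im = as_tensor(x), as_tensor(w_re), as_tensor(w_im)
    if x.data.shape != w_re.data.shape or w_re.data.shape != w_im.data.shape:
        raise ValueError(
            f"filter shape {w_re.data.shape} does not match signal {x.data.shape}"
        )
    w = w_re.data + 1j * w_im.data
    u = np.fft.fftn(x.data, axes=axes)
    out = np.real(np.fft.ifftn(w * u, axes=axes))

    def backward(g):
        gx = np.real(np.fft.ifftn(np.conj(w) * np.fft.fftn(g, axes=axes), axes=axes))
        accumulate(x, gx)
        if w_re.requires_grad or w_im.requires_grad:
            c = np.fft.ifftn(g, axes=axes) * u
            accumulate(w_re, np.real(c))
            accumulate(w_im, -np.imag(c))

    return make_op(out, (x, w_re, w_im), backward)


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """Expand a padded ``(H+2p, W+2p, D+2p, C)`` map to ``(H·W·D, k³·C)``."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(0, 1, 2))
    # win: (H, W, D, C, k, k, k) -> (H, W, D, k, k, k, C)
    win = np.moveaxis(win, 3, 6)
    h, w, d = win.shape[:3]
    return np.ascontiguousarray(win).reshape(h * w * d, -1), (h, w, d)


def conv3d(x, weight, bias=None, kernel: int = 3) -> Tensor:
    """Same-padding stride-1 3D convolution via im2col.

    ``x``: ``(H, W, D, C_in)``; ``weight``: ``(k³·C_in, C_out)`` with row
    order (kh, kw, kd, channel); ``bias``: ``(C_out,)`` or None.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    bias = as_tensor(bias) if bias is not None else None
    k = kernel
    p = k // 2
    cin = x.data.shape[3]
    if weight.data.shape[0] != k ** 3 * cin:
        raise ValueError(
            f"weight rows {weight.data.shape[0]} != k^3*C_in {k ** 3 * cin}"
        )
    xp = np.pad(x.data, ((p, p), (p, p), (p, p), (0, 0)))
    cols, (h, w, d) = _im2col(xp, k)
    y = cols @ weight.data
    if bias is not None:
        y = y + bias.data
    cout = weight.data.shape[1]
    out = y.reshape(h, w, d, cout)

    def backward(g):
        gflat = g.reshape(-1, cout)
        accumulate(weight, cols.T @ gflat)
        if bias is not None:
            accumulate(bias, gflat.sum(axis=0))
        if x.requires_grad:
            # grad wrt x = full correlation of g with the flipped kernel
            wk = weight.data.reshape(k, k, k, cin, cout)
            wk = wk[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3).reshape(-1, cin)
            gp = np.pad(g, ((p, p), (p, p), (p, p), (0, 0)))
            gcols, _ = _im2col(gp, k)
            accumulate(x, (gcols @ wk).reshape(h, w, d, cin))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return make_op(out, parents, backward)


def up_conv3d(x, weight, bias=None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact 2× upsampling).

    Each input voxel maps linearly to a 2×2×2 output block: ``weight`` has
    shape ``(C_in, 8·C_out)`` (block order (dh, dw, dd, channel)).
    """
    x, weight = as_tensor(x), as_tensor(weight)
    bias = as_tensor(bias) if bias is not None else None
    h, w, d, cin = x.data.shape
    cout = weight.data.shape[1] // 8
    y = (x.data.reshape(-1, cin) @ weight.data).reshape(h, w, d, 2, 2, 2, cout)
    y = y.transpose(0, 3, 1, 4, 2, 5, 6).reshape(2 * h, 2 * w, 2 * d, cout)
    if bias is not None:
        y = y + bias.data

    def backward(g):
        gb = g.reshape(h, 2, w, 2, d, 2, cout).transpose(0, 2, 4, 1, 3, 5, 6)
        gflat = gb.reshape(-1, 8 * cout)
        accumulate(weight, x.data.reshape(-1, cin).T @ gflat)
        if bias is not None:
            accumulate(bias, g.reshape(-1, cout).sum(axis=0))
        accumulate(x, (gflat @ weight.data.T).reshape(h, w, d, cin))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return make_op(y, parents, backward)
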