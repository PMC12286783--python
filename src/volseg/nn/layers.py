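"""Network building blocks on top of the autodiff ops.

All layers operate on ``(H, W, D, C)`` feature maps or ``(N, K)`` token
matrices with channels last.  Parameters are float32 by default; tests that
need tight finite-difference agreement construct float64 parameters via
``dtype``.
"""

from __future__ import annotations

import numpy as np

from . import ops
from .autodiff import Tensor

__all__ = [
    "Module", "ModuleList", "Linear", "LayerNorm", "Mlp",
    "MultiHeadSelfAttention", "SpectralMixer", "PatchMerge",
    "ConvBlock", "UpConv",
]


class Module:
    """Parameter container with recursive registry (name -> Tensor)."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.parameters(prefix=f"{key}."))
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    out.update(m.parameters(prefix=f"{key}.{i}."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: np.array(v.data) for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)[:3]} "
                           f"extra={sorted(extra)[:3]}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data = np.array(state[k], dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


def _param(rng: np.random.Generator, shape, std: float | None,
           dtype=np.float32) -> Tensor:
    if std is None:  # fan-in scaled
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        std = 1.0 / np.sqrt(fan_in)
    data = rng.normal(0.0, std, size=shape).astype(dtype) if std > 0 else \
        np.zeros(shape, dtype=dtype)
    return Tensor(data, requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True,
                 std: float | None = None, dtype=np.float32):
        self.weight = _param(rng, (in_features, out_features), std, dtype)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype),
                           requires_grad=True) if bias else None

    def forward(self, x):
        y = ops.matmul(x, self.weight)
        if self.bias is not None:
            y = ops.add(y, self.bias)
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float32):
        self.gain = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def forward(self, x):
        return ops.layer_norm(x, self.gain, self.bias)


class Mlp(Module):
    """Two affine maps with a nonlinearity between; hidden = ratio · dim.

    ``activation`` is "gelu" (default) or "linear" (identity, used by tests
    that need the block to reduce to a pure affine map).
    """

    def __init__(self, dim: int, rng: np.random.Generator, ratio: float = 4.0,
                 activation: str = "gelu", dtype=np.float32):
        if activation not in ("gelu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        hidden = max(int(dim * ratio), 1)
        self.activation = activation
        self.fc1 = Linear(dim, hidden, rng, dtype=dtype)
        self.fc2 = Linear(hidden, dim, rng, dtype=dtype)

    def forward(self, x):
        h = self.fc1(x)
        if self.activation == "gelu":
            h = ops.gelu(h)
        return self.fc2(h)


class MultiHeadSelfAttention(Module):
    """Standard softmax(QKᵀ/√d_h)V attention over an (N, K) token matrix."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        if dim % heads:
            raise ValueError(f"embed dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng, dtype=dtype)
        self.proj = Linear(dim, dim, rng, dtype=dtype)

    def forward(self, tokens):
        n, k = tokens.shape
        h, dh = self.heads, self.head_dim
        qkv = self.qkv(tokens)                       # (N, 3K)
        qkv = qkv.reshape(n, 3, h, dh).transpose((1, 2, 0, 3))  # (3, h, N, dh)
        q = _take(qkv, 0)                            # (h, N, dh)
        kk = _take(qkv, 1)
        v = _take(qkv, 2)
        att = ops.matmul(q, kk.transpose((0, 2, 1)))  # (h, N, N)
        att = ops.mul(att, 1.0 / np.sqrt(dh))
        att = ops.softmax(att, axis=-1)
        out = ops.matmul(att, v)                      # (h, N, dh)
        out = out.transpose((1, 0, 2)).reshape(n, k)
        return self.proj(out)


def _take(t, index: int):
    """Select ``t[index]`` along axis 0 (differentiable)."""
    from .autodiff import accumulate, make_op

    def backward(g):
        full = np.zeros_like(t.data)
        full[index] = g
        accumulate(t, full)

    return make_op(t.data[index], (t,), backward)


class SpectralMixer(Module):
    """Learned per-frequency, per-channel complex filter (identity at init).

    The filter lives on a reference frequency grid fixed at construction;
    inputs on other grids are handled by nearest-normalised-frequency
    resampling of the filter, so one set of weights serves all window sizes.
    A channel-mixing output projection follows the inverse transform.
    """

    def __init__(self, ref_grid: tuple[int, int, int], dim: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.ref_grid = tuple(ref_grid)
        shape = self.ref_grid + (dim,)
        self.w_re = Tensor(np.ones(shape, dtype=dtype), requires_grad=True)
        self.w_im = Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)
        self.proj = Linear(dim, dim, rng, dtype=dtype)

    @staticmethod
    def _freq_indices(n: int, ref: int) -> np.ndarray:
        if n == ref:
            return np.arange(n)
        f = np.fft.fftfreq(n)[:, None]
        fr = np.fft.fftfreq(ref)[None, :]
        return np.argmin(np.abs(f - fr), axis=1)

    def forward(self, x):
        """``x``: (h, w, d, C) real feature map -> same shape."""
        h, w, d, _ = x.shape
        ih = self._freq_indices(h, self.ref_grid[0])
        iw = self._freq_indices(w, self.ref_grid[1])
        idd = self._freq_indices(d, self.ref_grid[2])
        wr = ops.gather_grid(self.w_re, ih, iw, idd)
        wi = ops.gather_grid(self.w_im, ih, iw, idd)
        mixed = ops.spectral_mix(x, wr, wi)
        return self.proj(mixed)


class PatchMerge(Module):
    """Concatenate 2×2×2 neighbourhoods and project: grid/2, channels up.

    Odd grid axes are zero-padded by one (recorded in the returned shape
    only; downstream crops against skip shapes).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.c_in, self.c_out = c_in, c_out
        self.reduce = Linear(8 * c_in, c_out, rng, dtype=dtype)

    def forward(self, x):
        h, w, d, c = x.shape
        pads = (h % 2, w % 2, d % 2)
        if any(pads):
            x = _pad_spatial(x, pads)
            h, w, d = h + pads[0], w + pads[1], d + pads[2]
        x = x.reshape(h // 2, 2, w // 2, 2, d // 2, 2, c)
        x = x.transpose((0, 2, 4, 1, 3, 5, 6))
        x = x.reshape(h // 2, w // 2, d // 2, 8 * c)
        return self.reduce(x)


def _pad_spatial(x, pads: tuple[int, int, int]):
    """Zero-pad at the high end of the three spatial axes (differentiable)."""
    from .autodiff import accumulate, make_op
    ph, pw, pd = pads
    out = np.pad(x.data, ((0, ph), (0, pw), (0, pd), (0, 0)))
    h, w, d, _ = x.data.shape

    def backward(g):
        accumulate(x, g[:h, :w, :d])

    return make_op(out, (x,), backward)


class ConvBlock(Module):
    """Two same-padding 3×3×3 convolutions, each followed by channel
    layer-norm and GELU (the decoder's refinement block).

    Setting ``norm_act = False`` turns the block into two plain
    convolutions, which lets tests configure it as an exact identity.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, dtype=np.float32):
        self.kernel = kernel
        self.norm_act = True
        k3 = kernel ** 3
        self.w1 = _param(rng, (k3 * c_in, c_out), None, dtype)
        self.b1 = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.norm1 = LayerNorm(c_out, dtype=dtype)
        self.w2 = _param(rng, (k3 * c_out, c_out), None, dtype)
        self.b2 = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.norm2 = LayerNorm(c_out, dtype=dtype)

    def forward(self, x):
        x = ops.conv3d(x, self.w1, self.b1, self.kernel)
        if self.norm_act:
            x = ops.gelu(self.norm1(x))
        x = ops.conv3d(x, self.w2, self.b2, self.kernel)
        if self.norm_act:
            x = ops.gelu(self.norm2(x))
        return x


class UpConv(Module):
    """Learned 2× upsampling (transposed convolution, kernel 2 stride 2)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.weight = _param(rng, (c_in, 8 * c_out), None, dtype)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def forward(self, x):
        return ops.up_conv3d(x, self.weight, self.bias)
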