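"""Hierarchical transformer encoder with Fourier-domain token mixing.

The encoder tokenises the input volume with a stride-``P`` patch embedding
(``P`` = 2 by default, so stage 1 sits at half the input resolution), then
runs four stages of pre-norm transformer blocks.  Each block mixes tokens
either through the adaptive Fourier path (default) — forward DFT over the
token grid, learned per-frequency complex filter, inverse DFT, channel
projection — or through multi-head self-attention.  Between stages a patch
merging layer concatenates 2×2×2 neighbourhoods and projects, halving the
grid and increasing the channel width.  With the default widths
(48, 96, 192, 384) an input of spatial size ``S`` produces stage outputs at
``S/2, S/4, S/8, S/16``: the feature pyramid consumed by the decoder.

Block ordering follows the pre-norm convention

    z′ = Mix(Norm(z)) + z
    z  = MLP(Norm(z′)) + z′

with the mix being the Fourier path or MSA depending on ``mixing_mode``.

A constant-resolution variant (12 layers at a single grid, width 768,
pyramid taps every quarter of the depth resampled to the hierarchical
geometry) is available through ``constant_resolution=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import patch_embed as pe
from .io import Volume
from .nn import (
    LayerNorm,
    Linear,
    Mlp,
    Module,
    ModuleList,
    MultiHeadSelfAttention,
    PatchMerge,
    SpectralMixer,
    Tensor,
    ops,
)

__all__ = ["EncoderConfig", "TransformerBlock", "AfnoEncoder", "trace_stage_shapes"]

MIXING_MODES = ("afno_3d", "afno_1d", "msa_only")


@dataclass
class EncoderConfig:
    """Architecture hyper-parameters of the encoder.

    ``patch_size`` is the tokenisation stride: 2 gives the documented
    half-resolution first stage.  ``base_input_shape`` is the reference
    spatial size used to allocate positional tables and spectral filters;
    other input sizes are served by nearest-index resampling of those
    tables, so the same weights run on any window size.
    """

    patch_size: int = 2
    stage_channels: tuple[int, ...] = (48, 96, 192, 384)
    blocks_per_stage: tuple[int, ...] = (2, 2, 2, 2)
    heads: tuple[int, ...] = (3, 6, 12, 24)
    mixing_mode: str = "afno_3d"
    mlp_ratio: float = 4.0
    constant_resolution: bool = False
    constant_dim: int = 768
    constant_layers: int = 12
    base_input_shape: tuple[int, int, int] = (64, 64, 64)

    def __post_init__(self) -> None:
        if self.mixing_mode not in MIXING_MODES:
            raise ValueError(
                f"mixing_mode must be one of {MIXING_MODES}, got {self.mixing_mode!r}"
            )
        n = len(self.stage_channels)
        if len(self.blocks_per_stage) != n or len(self.heads) != n:
            raise ValueError("stage_channels, blocks_per_stage and heads must "
                             "have equal length")
        if not self.constant_resolution and \
                any(a >= b for a, b in zip(self.stage_channels, self.stage_channels[1:])):
            raise ValueError("stage_channels must be strictly increasing in "
                             "hierarchical mode")
        if self.patch_size < 1 or (self.patch_size & (self.patch_size - 1)):
            raise ValueError("patch_size must be a positive power of two")

    @property
    def num_stages(self) -> int:
        return len(self.stage_channels)

    def min_input_size(self) -> int:
        return self.patch_size * 2 ** self.num_stages

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        d = dict(d)
        for k in ("stage_channels", "blocks_per_stage", "heads",
                  "base_input_shape"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def trace_stage_shapes(config: EncoderConfig,
                       input_shape: tuple[int, int, int]
                       ) -> list[tuple[tuple[int, int, int], int]]:
    """Shape-only schedule of the feature pyramid (no computation).

    Returns ``[(spatial_shape, channels), ...]`` per stage for a given
    input spatial shape: stage ``s`` sits at ``input / (P · 2^s)`` grid
    positions, i.e. ``input/2^(s+1)`` voxels of context for ``P = 2``.
    """
    p = config.patch_size
    grid = tuple(-(-s // p) for s in input_shape)
    out = []
    for s, c in enumerate(config.stage_channels):
        out.append((grid, c))
        grid = tuple(-(-g // 2) for g in grid)
    return out


class TransformerBlock(Module):
    """Pre-norm block: token mixing then MLP, residuals outside the norms."""

    def __init__(self, dim: int, heads: int, mixing_mode: str,
                 ref_grid: tuple[int, int, int], rng: np.random.Generator,
                 mlp_ratio: float = 4.0, dtype=np.float32):
        self.mixing_mode = mixing_mode
        self.norm1 = LayerNorm(dim, dtype=dtype)
        if mixing_mode in ("afno_3d", "afno_1d"):
            if mixing_mode == "afno_1d":
                # literal 1D transform over the flattened token index
                ref_grid = (int(np.prod(ref_grid)), 1, 1)
            self.mixer = SpectralMixer(ref_grid, dim, rng, dtype=dtype)
        else:
            self.mixer = MultiHeadSelfAttention(dim, heads, rng, dtype=dtype)
        self.norm2 = LayerNorm(dim, dtype=dtype)
        self.mlp = Mlp(dim, rng, ratio=mlp_ratio, dtype=dtype)

    def _mix(self, x):
        h, w, d, c = x.shape
        if self.mixing_mode == "afno_3d":
            return self.mixer(x)
        if self.mixing_mode == "afno_1d":
            flat = x.reshape(h * w * d, 1, 1, c)
            return self.mixer(flat).reshape(h, w, d, c)
        flat = x.reshape(h * w * d, c)
        return self.mixer(flat).reshape(h, w, d, c)

    def forward(self, x):
        x = ops.add(x, self._mix(self.norm1(x)))
        x = ops.add(x, self.mlp(self.norm2(x)))
        return x


class AfnoEncoder(Module):
    """Four-stage (by default) hierarchical encoder producing a pyramid."""

    def __init__(self, config: EncoderConfig, in_channels: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.config = config
        self.in_channels = in_channels
        p = config.patch_size
        self.ref_token_grid = tuple(-(-s // p) for s in config.base_input_shape)
        if config.constant_resolution:
            self._init_constant(rng, dtype)
        else:
            self._init_hierarchical(rng, dtype)

    # -- construction --------------------------------------------------------
    def _make_pos_table(self, grid, dim, rng, dtype):
        data = rng.normal(0.0, 0.02, size=grid + (dim,)).astype(dtype)
        return Tensor(data, requires_grad=True)

    def _init_hierarchical(self, rng, dtype):
        cfg = self.config
        p = cfg.patch_size
        width = p ** 3 * self.in_channels
        self.embed = Linear(width, cfg.stage_channels[0], rng, dtype=dtype)
        self.pos_table = self._make_pos_table(self.ref_token_grid,
                                              cfg.stage_channels[0], rng, dtype)
        self.stages = ModuleList()
        self.merges = ModuleList()
        grid = self.ref_token_grid
        for s, c in enumerate(cfg.stage_channels):
            blocks = ModuleList(
                TransformerBlock(c, cfg.heads[s], cfg.mixing_mode, grid, rng,
                                 cfg.mlp_ratio, dtype)
                for _ in range(cfg.blocks_per_stage[s])
            )
            self.stages.append(_Stage(blocks))
            if s < cfg.num_stages - 1:
                self.merges.append(PatchMerge(c, cfg.stage_channels[s + 1],
                                              rng, dtype=dtype))
                grid = tuple(-(-g // 2) for g in grid)

    def _init_constant(self, rng, dtype):
        cfg = self.config
        p = cfg.patch_size
        width = p ** 3 * self.in_channels
        k = cfg.constant_dim
        self.embed = Linear(width, k, rng, dtype=dtype)
        self.pos_table = self._make_pos_table(self.ref_token_grid, k, rng, dtype)
        self.blocks = ModuleList(
            TransformerBlock(k, max(cfg.heads[-1], 1), cfg.mixing_mode,
                             self.ref_token_grid, rng, cfg.mlp_ratio, dtype)
            for _ in range(cfg.constant_layers)
        )
        # taps every quarter of the depth, resampled to the hierarchical
        # geometry (stage s: grid/2^s, stage_channels[s])
        self.resamplers = ModuleList()
        for s, c in enumerate(cfg.stage_channels):
            chain = ModuleList()
            if s == 0:
                chain.append(Linear(k, c, rng, dtype=dtype))
            else:
                chain.append(PatchMerge(k, c, rng, dtype=dtype))
                for _ in range(s - 1):
                    chain.append(PatchMerge(c, c, rng, dtype=dtype))
            self.resamplers.append(_Resampler(chain, linear_first=(s == 0)))

    # -- forward -------------------------------------------------------------
    def _check_size(self, shape) -> None:
        m = self.config.min_input_size()
        if any(s < m for s in shape):
            raise ValueError(
                f"input spatial shape {tuple(shape)} below the minimum "
                f"{m} per axis required by {self.config.num_stages} stages "
                f"at patch size {self.config.patch_size}"
            )

    def _tokens(self, data: np.ndarray):
        cfg = self.config
        patches, grid, pads = pe.partition_patches(data, cfg.patch_size)
        x = self.embed(Tensor(patches))
        dim = x.shape[1]
        x = x.reshape(*grid, dim)
        idx = [_spatial_indices(grid[a], self.ref_token_grid[a]) for a in range(3)]
        pos = ops.gather_grid(self.pos_table, *idx)
        return ops.add(x, pos), grid, pads

    def forward(self, vol: Volume | np.ndarray):
        """Run the encoder; returns ``(pyramid, pad_amounts)``.

        ``pyramid`` is a list of 4D tensors, one per stage, finest first.
        """
        data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
        if data.ndim == 3:
            data = data[..., np.newaxis]
        self._check_size(data.shape[:3])
        if self.config.constant_resolution:
            return self._forward_constant(data)
        x, grid, pads = self._tokens(data)
        pyramid = []
        for s, stage in enumerate(self.stages):
            x = stage(x)
            pyramid.append(x)
            if s < len(self.merges):
                x = self.merges[s](x)
        return pyramid, pads

    def _forward_constant(self, data: np.ndarray):
        x, grid, pads = self._tokens(data)
        n_blocks = len(self.blocks)
        tap_at = {max(1, round(n_blocks * (s + 1) / len(self.resamplers))) - 1
                  for s in range(len(self.resamplers))}
        taps = []
        for i, block in enumerate(self.blocks):
            x = block(x)
            if i in tap_at:
                taps.append(x)
        while len(taps) < len(self.resamplers):  # degenerate very-shallow case
            taps.append(x)
        pyramid = [rs(t) for rs, t in zip(self.resamplers, taps)]
        return pyramid, pads


class _Stage(Module):
    def __init__(self, blocks: ModuleList):
        self.blocks = blocks

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x


class _Resampler(Module):
    def __init__(self, chain: ModuleList, linear_first: bool):
        self.chain = chain
        self.linear_first = linear_first

    def forward(self, x):
        for m in self.chain:
            x = m(x)
        return x


def _spatial_indices(n: int, ref: int) -> np.ndarray:
    """Nearest-index map from a grid of size n onto the reference grid."""
    if n == ref:
        return np.arange(n)
    return np.clip(np.floor((np.arange(n) + 0.5) * ref / n), 0, ref - 1
                   ).astype(np.intp)
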