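"""Patch partitioning and linear token embedding.

A volume ``(H, W, D, C)`` is cut into non-overlapping cubic patches of side
``P`` (the volume is zero-padded at the high end of each axis up to the next
multiple of ``P``; the pad amounts are recorded so the decoder can crop).
Patches are enumerated in row-major order over the patch grid ``(h, w, d)``
— the D index varies fastest, H slowest — and each patch is flattened in
``(patch-h, patch-w, patch-d, channel)`` order.  Tokens are then

    E_patch = Flatten(x_v) · W_proj + E_pos

i.e. a linear projection of each flattened patch plus a learned positional
table with one row per 3D grid position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Volume

__all__ = [
    "EmbeddingParams",
    "TokenSequence",
    "partition_patches",
    "unpartition_patches",
    "embed_patches",
    "make_embedding_params",
]


@dataclass
class EmbeddingParams:
    """Projection matrix, positional table and geometry of the embedding."""

    W_proj: np.ndarray  # (P³·C, K)
    E_pos: np.ndarray   # (N, K)
    patch_size: int
    embed_dim: int

    def __post_init__(self) -> None:
        self.W_proj = np.asarray(self.W_proj)
        self.E_pos = np.asarray(self.E_pos)
        if self.W_proj.ndim != 2 or self.E_pos.ndim != 2:
            raise ValueError("W_proj and E_pos must be matrices")
        if self.W_proj.shape[1] != self.embed_dim or \
                self.E_pos.shape[1] != self.embed_dim:
            raise ValueError("embedding width mismatch")
        if not (np.isfinite(self.W_proj).all() and np.isfinite(self.E_pos).all()):
            raise ValueError("embedding parameters contain non-finite entries")


@dataclass
class TokenSequence:
    """``(N, K)`` token matrix plus its 3D token-grid geometry."""

    tokens: np.ndarray
    grid: tuple[int, int, int]
    patch_size: int
    pad_amounts: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        h, w, d = self.grid
        if self.tokens.shape[0] != h * w * d:
            raise ValueError(
                f"token count {self.tokens.shape[0]} != grid product {h * w * d}"
            )
        if not np.isfinite(self.tokens).all():
            raise ValueError("tokens contain non-finite entries")


def _pad_to_multiple(data: np.ndarray, p: int):
    shape = data.shape[:3]
    pads = tuple((-s) % p for s in shape)
    if any(pads):
        data = np.pad(data, tuple((0, q) for q in pads) + ((0, 0),))
    return data, pads


def partition_patches(vol: Volume | np.ndarray, patch_size: int):
    """Cut a volume into flattened non-overlapping cubic patches.

    Returns ``(patches, grid, pad_amounts)`` where ``patches`` is
    ``(N, P³·C)`` with the enumeration and flattening orders documented in
    the module docstring.
    """
    p = int(patch_size)
    if p <= 0:
        raise ValueError(f"patch size must be >= 1, got {patch_size}")
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    data, pads = _pad_to_multiple(data, p)
    hh, ww, dd, c = data.shape
    grid = (hh // p, ww // p, dd // p)
    x = data.reshape(grid[0], p, grid[1], p, grid[2], p, c)
    x = x.transpose(0, 2, 4, 1, 3, 5, 6)  # (h, w, d, ph, pw, pd, C)
    patches = x.reshape(np.prod(grid), p ** 3 * c)
    return patches, grid, pads


def unpartition_patches(patches: np.ndarray, grid: tuple[int, int, int],
                        patch_size: int, channels: int,
                        pad_amounts: tuple[int, int, int] = (0, 0, 0)
                        ) -> np.ndarray:
    """Inverse of :func:`partition_patches`; crops the recorded padding."""
    p = int(patch_size)
    h, w, d = grid
    x = patches.reshape(h, w, d, p, p, p, channels)
    x = x.transpose(0, 3, 1, 4, 2, 5, 6).reshape(h * p, w * p, d * p, channels)
    ph, pw, pd = pad_amounts
    return x[: h * p - ph, : w * p - pw, : d * p - pd]


def embed_patches(patches: np.ndarray, params: EmbeddingParams,
                  grid: tuple[int, int, int],
                  pad_amounts: tuple[int, int, int] = (0, 0, 0)
                  ) -> TokenSequence:
    """Project flattened patches and add positional encodings."""
    patches = np.asarray(patches)
    if patches.shape[1] != params.W_proj.shape[0]:
        raise ValueError(
            f"patch width {patches.shape} incompatible with projection "
            f"{params.W_proj.shape}"
        )
    if patches.shape[0] != params.E_pos.shape[0]:
        raise ValueError(
            f"token count {patches.shape[0]} != positional rows "
            f"{params.E_pos.shape[0]}"
        )
    tokens = patches @ params.W_proj + params.E_pos
    return TokenSequence(tokens=tokens, grid=tuple(grid),
                         patch_size=params.patch_size,
                         pad_amounts=tuple(pad_amounts))


def make_embedding_params(patch_size: int, channels: int, embed_dim: int,
                          grid: tuple[int, int, int],
                          seed: int = 0, pos_std: float = 0.02
                          ) -> EmbeddingParams:
    """Random init: fan-in-scaled projection, N(0, 0.02) positional table."""
    rng = np.random.default_rng(seed)
    width = patch_size ** 3 * channels
    n = int(np.prod(grid))
    w = rng.normal(0.0, 1.0 / np.sqrt(width), size=(width, embed_dim))
    e = rng.normal(0.0, pos_std, size=(n, embed_dim))
    return EmbeddingParams(W_proj=w, E_pos=e, patch_size=patch_size,
                           embed_dim=embed_dim)
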