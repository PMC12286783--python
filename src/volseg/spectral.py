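"""Functional Fourier path: DFT, adaptive modulation, inverse DFT.

These are the three steps of the adaptive Fourier mixing applied to token
features:

    F(k)      = Σₙ e(n) · exp(−2πi·nk/N)          (forward transform)
    F_mod(k)  = F(k) · W(k)                        (learned filter)
    e′(n)     = (1/N) Σₖ F_mod(k) · exp(+2πi·nk/N) (inverse transform)

For real inputs the spectrum is stored on the half grid of the last
transformed axis (Hermitian symmetry is implicit in the storage), computed
with ``numpy.fft.rfft``/``rfftn``.  The 3D mode applies the separable
transform along the three token-grid axes per channel; the 1D mode applies
the literal single-index transform over the flattened token sequence.

The learnable, autodiff-aware version of this path lives in
:class:`volseg.nn.layers.SpectralMixer`; this module is the reference
functional form used by the encoder tests and by unit filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Spectrum",
    "SpectralFilter",
    "dft",
    "idft",
    "modulate",
    "unit_filter",
    "afno_mix",
]

_RESIDUE_TOL = 1e-8


@dataclass
class Spectrum:
    """Half-spectrum complex coefficients over frequency × channel.

    ``coeffs`` has shape ``grid[:-1] + (grid[-1]//2 + 1, C)`` in 3D mode or
    ``(N//2 + 1, C)`` in 1D mode; ``source_grid`` records the real-domain
    shape needed to invert.
    """

    coeffs: np.ndarray
    source_grid: tuple[int, ...]
    mode: str = "3d"  # "3d" | "1d"


@dataclass
class SpectralFilter:
    """Complex weights, one per retained frequency index per channel."""

    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.complex128)


def dft(signal: np.ndarray, mode: str = "3d") -> Spectrum:
    """Forward transform of a token feature array.

    ``signal``: ``(h, w, d, C)`` in 3D mode (transform over the three grid
    axes) or ``(N, C)`` in 1D mode (transform over the token index).
    """
    signal = np.asarray(signal)
    if signal.size == 0:
        raise ValueError("empty signal")
    if mode == "3d":
        if signal.ndim != 4:
            raise ValueError(f"3d mode expects (h, w, d, C), got {signal.shape}")
        coeffs = np.fft.rfftn(signal, axes=(0, 1, 2))
        return Spectrum(coeffs=coeffs, source_grid=signal.shape[:3], mode="3d")
    if mode == "1d":
        if signal.ndim != 2:
            raise ValueError(f"1d mode expects (N, C), got {signal.shape}")
        coeffs = np.fft.rfft(signal, axis=0)
        return Spectrum(coeffs=coeffs, source_grid=(signal.shape[0],), mode="1d")
    raise ValueError(f"unknown mode {mode!r}")


def idft(spec: Spectrum) -> np.ndarray:
    """Inverse transform back to the real domain.

    The half-spectrum storage enforces Hermitian symmetry, so the imaginary
    residue of the inverse is structurally zero and the output is real.
    """
    if spec.mode == "3d":
        return np.fft.irfftn(spec.coeffs, s=spec.source_grid, axes=(0, 1, 2))
    return np.fft.irfft(spec.coeffs, n=spec.source_grid[0], axis=0)


def modulate(spec: Spectrum, filt: SpectralFilter) -> Spectrum:
    """Elementwise complex product ``F_mod(k) = F(k) · W(k)``."""
    if filt.W.shape != spec.coeffs.shape:
        raise ValueError(
            f"filter shape {filt.W.shape} != spectrum shape {spec.coeffs.shape}"
        )
    return Spectrum(coeffs=spec.coeffs * filt.W, source_grid=spec.source_grid,
                    mode=spec.mode)


def unit_filter(spec: Spectrum) -> SpectralFilter:
    """The identity filter W(k) = 1 for a given spectrum shape."""
    return SpectralFilter(W=np.ones_like(spec.coeffs))


def afno_mix(tokens: np.ndarray, filt: SpectralFilter,
             grid: tuple[int, int, int], mode: str = "3d",
             residual: bool = True) -> np.ndarray:
    """Full mixing step: transform, modulate, invert, (residual add).

    ``tokens`` is an ``(N, K)`` matrix with ``N = h·w·d``; in 3D mode it is
    reshaped onto its token grid and transformed separably per channel.  The
    imaginary residue of the inverse must stay below 1e-8 (it is zero by
    construction with half-spectrum storage; the assertion guards the
    contract).
    """
    tokens = np.asarray(tokens)
    n, k = tokens.shape
    if int(np.prod(grid)) != n:
        raise ValueError(f"grid {grid} incompatible with {n} tokens")
    if mode == "3d":
        x = tokens.reshape(*grid, k)
    elif mode == "1d":
        x = tokens
    else:
        raise ValueError(f"unknown mode {mode!r}")
    spec = dft(x, mode=mode)
    mixed = idft(modulate(spec, filt))
    # irfft output is exactly real; the residue check is on the full inverse
    residue = np.abs(np.imag(np.asarray(mixed, dtype=np.complex128))).max()
    if residue >= _RESIDUE_TOL:  # pragma: no cover - structurally impossible
        raise FloatingPointError(f"imaginary residue {residue} >= {_RESIDUE_TOL}")
    mixed = np.real(mixed).reshape(n, k)
    return tokens + mixed if residual else mixed
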