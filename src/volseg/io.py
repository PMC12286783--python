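"""Medical volume I/O and intensity normalisation.

Volumes are held as rank-4 float arrays indexed ``(H, W, D, C)`` — channel
axis last, one fixed convention for the whole package — together with the
voxel spacing in millimetres along the three spatial axes.  Label maps are
rank-3 integer arrays on the same grid.  Files are NIfTI-1 (``.nii`` /
``.nii.gz``) read and written through :mod:`nibabel`; only the voxel spacing
from the header is interpreted, any further affine/orientation information is
carried along as opaque metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "normalize_zscore",
]


@dataclass
class Volume:
    """A multi-channel 3D image.

    Parameters
    ----------
    data:
        Array of shape ``(H, W, D, C)``; intensities in arbitrary units.
    spacing:
        Physical size of one voxel in mm along H, W, D (all positive).
    origin_note:
        Free-text provenance string (e.g. source filename).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_note: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(
                f"Volume data must be rank 3 or 4, got rank {self.data.ndim}"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        n_nan = int(np.isnan(self.data).sum())
        if n_nan:
            raise ValueError(f"volume contains {n_nan} NaN voxel value(s)")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def num_channels(self) -> int:
        return self.data.shape[3]


@dataclass
class LabelMap:
    """An integer class map aligned to a :class:`Volume` grid.

    ``labels`` has shape ``(H, W, D)`` with values in ``0..num_classes-1``;
    class 0 is background by convention.
    """

    labels: np.ndarray
    num_classes: int | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"labels must be rank 3, got rank {arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            frac = arr[arr != np.floor(arr)]
            if frac.size:
                raise ValueError(
                    f"labels contain {frac.size} non-integer value(s), e.g. {frac.flat[0]}"
                )
            arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            raise ValueError(f"labels contain negative value(s), min={arr.min()}")
        self.labels = arr
        if self.num_classes is None:
            self.num_classes = int(arr.max()) + 1 if arr.size else 1
        self.num_classes = max(int(self.num_classes), 2)
        if arr.size and arr.max() >= self.num_classes:
            raise ValueError(
                f"max label {arr.max()} >= num_classes {self.num_classes}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def _spacing_from_header(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI file into a :class:`Volume`.

    A 3D file yields one channel; a 4D file maps its last axis to channels.
    NaN voxels are rejected with an error naming the affected count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D NIfTI, got rank {data.ndim}: {path}")
    return Volume(data=data, spacing=_spacing_from_header(img), origin_note=str(path))


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` as float32 NIfTI with spacing in the header."""
    path = Path(path)
    data = np.ascontiguousarray(vol.data, dtype=np.float32)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(vol.spacing) + (1.0,) if data.ndim == 4 else vol.spacing)
    nib.save(img, str(path))


def read_labels(path: str | Path, num_classes: int | None = None) -> LabelMap:
    """Read an integer label map; fractional or negative voxels are errors.

    When ``num_classes`` is not supplied it is inferred as ``max label + 1``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label NIfTI, got rank {data.ndim}: {path}")
    return LabelMap(labels=data, num_classes=num_classes,
                    spacing=_spacing_from_header(img))


def write_labels(lm: LabelMap, path: str | Path) -> None:
    """Write a :class:`LabelMap` as an unsigned-integer NIfTI."""
    path = Path(path)
    dtype = np.uint8 if lm.num_classes <= 256 else np.uint16
    data = np.ascontiguousarray(lm.labels, dtype=dtype)
    affine = np.diag(list(lm.spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def normalize_zscore(vol: Volume, eps: float = 1e-8) -> Volume:
    """Z-score normalise each channel over the whole volume.

    Per channel the output is ``(x - mean) / std`` with moments computed over
    all voxels of that channel.  A degenerate channel (std below ``eps``)
    maps to all zeros rather than dividing by ~0.
    """
    out = np.empty_like(vol.data, dtype=np.float32)
    for c in range(vol.num_channels):
        ch = vol.data[..., c].astype(np.float64)
        std = ch.std()
        if std < eps:
            out[..., c] = 0.0
        else:
            out[..., c] = ((ch - ch.mean()) / std).astype(np.float32)
    return Volume(data=out, spacing=vol.spacing,
                  origin_note=f"zscore({vol.origin_note})")
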