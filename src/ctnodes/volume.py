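"""Core containers: CT volumes and lesion label maps, with NIfTI-1 I/O.

Arrays are ordered ``(z, y, x)`` with axis 0 the axial (slice) direction;
``spacing`` is the voxel size in mm per axis in the same order.  On disk the
conventional NIfTI axis order ``(x, y, z)`` is used, so arrays are transposed
on read/write and the spacing is encoded in the affine diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["CtVolume", "LesionLabelMap", "read_volume", "read_label_map"]


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing!r}")
    return spacing


@dataclass
class CtVolume:
    """A 3D CT volume in Hounsfield units with per-axis voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CT volume contains non-finite values")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        return self.spacing[1], self.spacing[2]

    def to_nifti(self, path: str | Path) -> None:
        _write_nifti(self.data.astype(np.float32), self.spacing, path)


@dataclass
class LesionLabelMap:
    """Integer lesion labels aligned to a :class:`CtVolume`; 0 is background."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.array_equal(data, np.round(data)):
                raise ValueError("label map must be integer-valued")
            data = data.astype(np.int32)
        if data.min() < 0:
            raise ValueError("label map must be non-negative")
        self.data = data.astype(np.int32)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.data)
        return lab[lab > 0]

    def binary(self) -> np.ndarray:
        return self.data > 0

    def to_nifti(self, path: str | Path) -> None:
        _write_nifti(self.data.astype(np.int16), self.spacing, path)


def _write_nifti(data_zyx: np.ndarray, spacing, path: str | Path) -> None:
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    img = nib.Nifti1Image(np.transpose(data_zyx, (2, 1, 0)), affine)
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    nib.save(img, str(path))


def _read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI image, got shape {data.shape}")
    zx, zy, zz = img.header.get_zooms()[:3]
    return np.ascontiguousarray(np.transpose(data, (2, 1, 0))), (float(zz), float(zy), float(zx))


def read_volume(path: str | Path) -> CtVolume:
    """Read a CT volume from NIfTI-1, returning ``(z, y, x)``-ordered HU data."""
    data, spacing = _read_nifti(path)
    return CtVolume(data.astype(np.float32), spacing)


def read_label_map(path: str | Path, spacing_override=None) -> LesionLabelMap:
    """Read an integer lesion label map from NIfTI-1."""
    data, spacing = _read_nifti(path)
    return LesionLabelMap(np.rint(data).astype(np.int32), spacing_override or spacing)
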