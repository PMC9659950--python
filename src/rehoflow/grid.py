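"""Gridded data containers (4D BOLD volumes, 3D statistic maps) and NIfTI-1 I/O.

All stages of the pipeline exchange data through :class:`Volume4D` (a masked
4D BOLD grid with its affine and TR) and :class:`StatMap` (a 3D scalar map on
the same grid: ReHo, mReHo, z, r, Fisher-z FC or t values).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume4D", "StatMap", "voxel_sizes"]


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths in mm along the three spatial axes."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass
class Volume4D:
    """A 4D BOLD series on a regular grid.

    Parameters
    ----------
    data : (X, Y, Z, T) array
        BOLD intensities.
    affine : (4, 4) array
        Voxel-to-mm map (must be invertible).
    tr : float
        Repetition time in seconds.
    mask : (X, Y, Z) bool array
        Brain mask; analysis is restricted to in-mask voxels.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (X,Y,Z,T), got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match spatial grid")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        return voxel_sizes(self.affine)

    def in_mask_series(self) -> np.ndarray:
        """(n_voxels, T) view of the in-mask time series."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return replace(self, data=data)

    def save(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine), str(path))
        if mask_path is not None:
            nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), str(mask_path))

    @classmethod
    def load(cls, path: str | Path, mask: np.ndarray | str | Path, tr: float | None = None) -> "Volume4D":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(dtype=np.float32))
        if isinstance(mask, (str, Path)):
            mask = np.asarray(nib.load(str(mask)).get_fdata()) > 0.5
        if tr is None:
            tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
        return cls(data=data, affine=img.affine, tr=float(tr), mask=np.asarray(mask, dtype=bool))


@dataclass
class StatMap:
    """A 3D scalar map sharing the grid of the volumes it was derived from."""

    values: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("StatMap values must be 3D")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, label: str | None = None) -> "StatMap":
        return StatMap(values=values, affine=self.affine, mask=self.mask,
                       label=self.label if label is None else label)

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path, mask: np.ndarray, label: str = "") -> "StatMap":
        img = nib.load(str(path))
        return cls(values=np.asarray(img.get_fdata(dtype=np.float32)), affine=img.affine,
                   mask=np.asarray(mask, dtype=bool), label=label)
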