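"""Minimal 3-D volume and ROI-mask containers with NIfTI-1 I/O.

A :class:`Volume` is a scalar grid plus its voxel spacing in millimetres.
Voxel indices are 0-based; the world coordinate of voxel ``(i, j, k)`` is
``origin + index * spacing`` (first voxel centre at the origin).  All
spatial parameters elsewhere in the package are expressed in mm and
converted to voxels through ``spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "RoiMask"]


@dataclass
class Volume:
    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def isotropic(self) -> bool:
        s = self.spacing
        return np.isclose(s[0], s[1]) and np.isclose(s[1], s[2])

    def copy_with(self, data: np.ndarray, spacing=None) -> "Volume":
        return Volume(np.asarray(data, dtype=float),
                      self.spacing if spacing is None else spacing,
                      self.origin)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine()), path)

    @classmethod
    def load(cls, path: str) -> "Volume":
        img = nib.load(path)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=float), zooms, origin)


@dataclass
class RoiMask:
    """Binary region of interest aligned voxel-for-voxel to a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not self.data.any()

    def copy_with(self, data: np.ndarray, spacing=None) -> "RoiMask":
        return RoiMask(np.asarray(data) > 0,
                       self.spacing if spacing is None else spacing,
                       self.origin)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine()), path)

    @classmethod
    def load(cls, path: str) -> "RoiMask":
        img = nib.load(path)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return cls(np.asarray(img.dataobj) > 0, zooms, origin)
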