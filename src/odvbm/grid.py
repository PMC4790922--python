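"""Grid geometry and tissue-density volumes.

All voxelwise computation in this package operates on :class:`VolumeMap`
objects: a 3D scalar field of tissue density (RAVENS-style, mass-preserving,
dimensionless and non-negative) on a common grid, together with a boolean
analysis mask.  Cohorts are flattened to ``(n_subjects, n_in_mask_voxels)``
matrices with :func:`stack_cohort` for the statistical machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GridGeometry",
    "VolumeMap",
    "stack_cohort",
    "unstack_values",
    "load_volume",
    "save_volume",
]


@dataclass(frozen=True)
class GridGeometry:
    """Voxel grid with a voxel-index -> mm affine mapping.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis, all >= 1.
    voxel_size : tuple of float
        Edge length of a voxel along each axis, in mm.
    origin : tuple of float
        mm coordinate of voxel index (0, 0, 0).
    """

    shape: tuple
    voxel_size: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        org = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size entries must be > 0, got {vs}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "origin", org)

    @classmethod
    def centered(cls, shape, voxel_size=(1.0, 1.0, 1.0)):
        """Grid whose mm origin puts (0,0,0) at the geometric center.

        With the midline at x = 0, left/right hemisphere assignment by the
        sign of x is well defined (negative x = left, as in stereotaxic
        reporting conventions).
        """
        shape = tuple(int(s) for s in shape)
        voxel_size = tuple(float(v) for v in voxel_size)
        origin = tuple(-(s - 1) / 2.0 * v for s, v in zip(shape, voxel_size))
        return cls(shape=shape, voxel_size=voxel_size, origin=origin)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (diagonal scaling + origin)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_mm(self, ijk) -> np.ndarray:
        """Map voxel indices (..., 3) to mm coordinates (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def mm_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.voxel_size)


@dataclass
class VolumeMap:
    """One subject's tissue-density image on a grid, with an analysis mask."""

    grid: GridGeometry
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
            )
        if not self.mask.any():
            raise ValueError("mask is empty")
        if np.any(self.values[self.mask] < 0):
            raise ValueError("tissue density must be >= 0 inside the mask")

    def copy_with(self, values: np.ndarray) -> "VolumeMap":
        return VolumeMap(grid=self.grid, values=values, mask=self.mask)


def stack_cohort(maps) -> np.ndarray:
    """Flatten a cohort of volumes to a (n_subjects, n_in_mask_voxels) matrix.

    Column order is C-order scan of the shared mask (``np.flatnonzero``); all
    estimators in this package use the same ordering.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("empty cohort")
    mask = maps[0].mask
    for m in maps[1:]:
        if m.values.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("all volumes in a cohort must share one grid and mask")
    return np.stack([m.values[mask] for m in maps])


def unstack_values(flat: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Scatter a flat in-mask vector back into a 3D field."""
    out = np.full(mask.shape, fill, dtype=np.float64)
    out[mask] = flat
    return out


def save_volume(path, values: np.ndarray, grid: GridGeometry) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def load_volume(path, mask: np.ndarray | None = None) -> VolumeMap:
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=np.float64)
    aff = img.affine
    grid = GridGeometry(
        shape=values.shape,
        voxel_size=tuple(np.abs(np.diag(aff)[:3])),
        origin=tuple(aff[:3, 3]),
    )
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return VolumeMap(grid=grid, values=np.clip(values, 0, None), mask=mask)
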