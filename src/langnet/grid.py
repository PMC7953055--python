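"""Voxel-grid geometry shared by the phantom simulator, ROI extraction and
lesion mapping: a rectilinear grid with per-axis voxel size and a physical
origin, mapping between MNI-style mm coordinates and 0-based voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "DEFAULT_PHANTOM_GRID", "sphere_voxels"]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid: shape, voxel size (mm) and origin (mm).

    NIfTI convention: the physical position of voxel (i, j, k) is
    origin + index * voxel_size, so the origin is the position of voxel
    (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be three positive integers")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel dimensions must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def mm_to_voxel(self, xyz_mm) -> np.ndarray:
        """Nearest voxel index for a physical coordinate (clipped to grid)."""
        xyz = np.asarray(xyz_mm, dtype=float)
        idx = np.rint(
            (xyz - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)
        ).astype(int)
        return np.clip(idx, 0, np.asarray(self.shape) - 1)

    def voxel_to_mm(self, ijk) -> np.ndarray:
        idx = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.voxel_size_mm)

    def contains_mm(self, xyz_mm) -> bool:
        xyz = np.asarray(xyz_mm, dtype=float)
        lo = np.asarray(self.origin_mm)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.voxel_size_mm)
        return bool(np.all(xyz >= lo) and np.all(xyz <= hi))

    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 affine (diagonal)."""
        aff = np.eye(4)
        for a in range(3):
            aff[a, a] = self.voxel_size_mm[a]
            aff[a, 3] = self.origin_mm[a]
        return aff


# Covers the MNI bounding box of the canonical LN peaks (x -57..60,
# y -81..24, z -42..57 mm) at 3 mm isotropic resolution with a margin.
DEFAULT_PHANTOM_GRID = GridSpec(
    shape=(48, 44, 40),
    voxel_size_mm=(3.0, 3.0, 3.0),
    origin_mm=(-75.0, -96.0, -54.0),
)


def sphere_voxels(grid: GridSpec, center_mm, radius_mm: float) -> np.ndarray:
    """Indices (n, 3) of voxels whose positions lie within ``radius_mm`` of
    a physical point.  Spheres extending outside the grid are truncated."""
    center = np.asarray(center_mm, dtype=float)
    vs = np.asarray(grid.voxel_size_mm)
    origin = np.asarray(grid.origin_mm)
    lo = np.maximum(np.ceil((center - radius_mm - origin) / vs).astype(int), 0)
    hi = np.minimum(
        np.floor((center + radius_mm - origin) / vs).astype(int),
        np.asarray(grid.shape) - 1,
    )
    if np.any(lo > hi):
        return np.zeros((0, 3), dtype=int)
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = grid.voxel_to_mm(idx)
    keep = np.sum((centers - center) ** 2, axis=1) <= radius_mm**2
    return idx[keep]
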