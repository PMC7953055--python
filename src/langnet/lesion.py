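"""Tumor mask handling: volumes, group overlap-density maps, and assignment
of a lesion to one of the four language subsystems (LF, LT, RF, RT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

from .grid import GridSpec
from .rois import SubsystemAtlas

__all__ = [
    "LesionMask",
    "tumor_volume",
    "overlap_map",
    "save_density_nifti",
    "assign_subsystem",
    "ellipsoid_mask",
]

logger = logging.getLogger(__name__)


@dataclass
class LesionMask:
    """A binary tumor volume-of-interest on a voxel grid."""

    data: np.ndarray  # 3-D, values in {0, 1}
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D voxel grid")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel dimensions must be positive")
        self.data = self.data.astype(np.uint8)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.data.shape, tuple(self.voxel_size_mm), tuple(self.origin_mm))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.grid.affine())
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LesionMask":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(data=(data > 0.5).astype(np.uint8), voxel_size_mm=zooms, origin_mm=origin)


def tumor_volume(mask: LesionMask) -> float:
    """Lesion volume in cm^3: nonzero-voxel count times voxel volume."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0


def overlap_map(masks: Sequence[LesionMask]) -> np.ndarray:
    """Voxelwise count of overlapping lesions (the group density map)."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].data.shape
    for m in masks[1:]:
        if m.data.shape != shape:
            raise ValueError(
                f"mask grid shapes differ: {m.data.shape} vs {shape}"
            )
    density = np.zeros(shape, dtype=np.int32)
    for m in masks:
        density += m.data
    return density


def save_density_nifti(
    density: np.ndarray, grid: GridSpec, path: str | Path
) -> None:
    img = nib.Nifti1Image(np.asarray(density, dtype=np.int32), grid.affine())
    nib.save(img, str(path))


@dataclass
class SubsystemAssignment:
    label: str  # LF | LT | RF | RT | unclassified
    overlaps: dict = field(default_factory=dict)  # subsystem -> voxel count
    ambiguous: bool = False


def assign_subsystem(
    mask: LesionMask,
    atlas: SubsystemAtlas,
    ambiguity_margin: float = 0.10,
) -> SubsystemAssignment:
    """Assign a tumor to the subsystem parcel it overlaps most.

    Ties are broken by the larger overlap *fraction* of the parcel, then
    lexicographically (with a logged warning).  A lesion whose top-two
    overlaps differ by less than ``ambiguity_margin`` (relative) is flagged
    ambiguous.  Zero overlap with every parcel yields "unclassified".
    """
    if atlas.parcels is None:
        raise ValueError("atlas has no voxel parcels; cannot assign a mask")
    overlaps: dict[str, int] = {}
    fractions: dict[str, float] = {}
    for label, parcel in atlas.parcels.items():
        if parcel.shape != mask.data.shape:
            raise ValueError(
                f"parcel {label!r} shape {parcel.shape} does not match mask "
                f"shape {mask.data.shape}"
            )
        ov = int(np.sum((parcel > 0) & (mask.data > 0)))
        overlaps[label] = ov
        parcel_size = int(np.sum(parcel > 0))
        fractions[label] = ov / parcel_size if parcel_size else 0.0
    best_count = max(overlaps.values(), default=0)
    if best_count == 0:
        logger.warning("lesion overlaps no subsystem parcel; unclassified")
        return SubsystemAssignment("unclassified", overlaps)
    tied = sorted(l for l, c in overlaps.items() if c == best_count)
    if len(tied) > 1:
        tied.sort(key=lambda l: (-fractions[l], l))
        logger.warning(
            "overlap tie between %s; broken by parcel fraction then name -> %s",
            tied, tied[0],
        )
    winner = tied[0]
    rest = sorted((c for l, c in overlaps.items() if l != winner), reverse=True)
    ambiguous = bool(rest and rest[0] > 0 and (best_count - rest[0]) / best_count < ambiguity_margin)
    if ambiguous:
        logger.warning(
            "ambiguous lesion: top-two subsystem overlaps within %.0f%% (%s)",
            100 * ambiguity_margin, overlaps,
        )
    return SubsystemAssignment(winner, overlaps, ambiguous)


def ellipsoid_mask(
    grid: GridSpec,
    center_mm,
    target_volume_cm3: float,
    axis_ratios: tuple[float, float, float] = (1.2, 1.0, 0.85),
) -> np.ndarray:
    """Binary ellipsoid of a requested volume, voxelized on ``grid``.

    The semi-axis scale is calibrated by bisection so the voxel count
    matches the target volume as closely as voxelization allows.  Raises if
    the calibrated ellipsoid's bounding box does not fit on the grid.
    """
    if target_volume_cm3 <= 0:
        raise ValueError("target volume must be positive")
    center = np.asarray(center_mm, dtype=float)
    ratios = np.asarray(axis_ratios, dtype=float)
    # nominal scale from the continuous ellipsoid volume 4/3 pi s^3 r1 r2 r3
    target_mm3 = target_volume_cm3 * 1000.0
    s0 = (target_mm3 / (4.0 / 3.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    target_n = target_mm3 / grid.voxel_volume_mm3

    axes_idx = [np.arange(n) for n in grid.shape]
    coords = [
        grid.origin_mm[a] + axes_idx[a] * grid.voxel_size_mm[a] - center[a]
        for a in range(3)
    ]

    def count(scale: float) -> np.ndarray:
        semi = scale * ratios
        q = (
            (coords[0][:, None, None] / semi[0]) ** 2
            + (coords[1][None, :, None] / semi[1]) ** 2
            + (coords[2][None, None, :] / semi[2]) ** 2
        )
        return q <= 1.0

    lo, hi = 0.5 * s0, 1.5 * s0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if count(mid).sum() < target_n:
            lo = mid
        else:
            hi = mid
    inside = count(hi)
    # prefer whichever bracket end lands closer to the target count
    inside_lo = count(lo)
    if abs(inside_lo.sum() - target_n) < abs(inside.sum() - target_n):
        inside, hi = inside_lo, lo
    semi = hi * ratios
    lo_mm = center - semi
    hi_mm = center + semi
    if not (grid.contains_mm(lo_mm) and grid.contains_mm(hi_mm)):
        raise ValueError(
            f"requested tumor ({target_volume_cm3} cm^3) does not fit on the "
            f"grid around {tuple(center)}"
        )
    return inside.astype(np.uint8)
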