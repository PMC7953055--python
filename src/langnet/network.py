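"""Desk-scale group spatial ICA and language-component selection.

Group ICA here follows the temporal-concatenation recipe: subject volumes
are masked, voxelwise centered, variance-normalized per subject,
concatenated along time, reduced
by PCA and unmixed with fixed-point (FastICA) iteration under symmetric
decorrelation.  Component maps are standardized to unit variance, so the
cluster-forming thresholds (default 5.0 cerebral, 3.0 cerebellar) are read
on the standardized-weight scale rather than as GLM T scores — a deliberate
approximation documented in the methods note.

The pipeline's default path uses the shipped canonical 10-node ROI set; the
ICA path is validated on synthetic phantoms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .grid import GridSpec, sphere_voxels

__all__ = [
    "ComponentMaps",
    "Cluster",
    "SphereRoi",
    "group_ica",
    "select_language_component",
    "threshold_clusters",
    "peak_rois",
]

logger = logging.getLogger(__name__)


@dataclass
class ComponentMaps:
    """Standardized spatial component maps plus the temporal mixing matrix."""

    maps: np.ndarray  # (k, x, y, z), zero mean / unit variance inside mask
    mixing: np.ndarray  # (total timepoints, k)
    mask: np.ndarray  # (x, y, z) bool, voxels entering the decomposition

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]


def group_ica(
    volumes: Sequence[np.ndarray],
    n_components: int = 30,
    seed: Optional[int] = None,
    mask: Optional[np.ndarray] = None,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> ComponentMaps:
    """Temporal-concatenation group spatial ICA.

    Parameters
    ----------
    volumes : list of (x, y, z, t) arrays, one per subject, on one grid.
    n_components : number of independent components to extract.
    seed : fixes the FastICA starting point; results are deterministic
        (up to component sign) under a fixed seed.
    mask : optional boolean brain mask; defaults to voxels with nonzero
        temporal variance in every subject.
    """
    if len(volumes) < 2:
        raise ValueError("group ICA needs at least 2 subjects")
    shape = volumes[0].shape[:3]
    for v in volumes:
        if v.ndim != 4 or v.shape[:3] != shape:
            raise ValueError("all volumes must be 4-D on one grid")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
        for v in volumes:
            mask &= v.std(axis=3) > 0
    n_vox = int(mask.sum())
    if n_vox < 10 * n_components:
        raise ValueError(
            f"{n_vox} masked voxels is too few for {n_components} components"
        )
    blocks = []
    for v in volumes:
        x = np.asarray(v, dtype=float)[mask]  # (voxels, t)
        x = x - x.mean(axis=1, keepdims=True)
        # subject-level variance normalization (voxelwise scaling would
        # erase the spatial amplitude structure the decomposition needs)
        sd = x.std()
        x = x / (sd if sd > 0 else 1.0)
        blocks.append(x)
    data = np.concatenate(blocks, axis=1)  # (voxels, total_t)
    if data.shape[1] < n_components:
        raise ValueError("fewer concatenated time points than components")
    pca = PCA(n_components=n_components, random_state=seed)
    reduced = pca.fit_transform(data)  # (voxels, k)
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",  # symmetric decorrelation
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform(reduced)  # (voxels, k)
        except ConvergenceWarning:
            raise RuntimeError(
                f"FastICA did not converge within {max_iter} iterations"
            ) from None
    # standardize each spatial map
    sources = (sources - sources.mean(axis=0)) / sources.std(axis=0)
    maps = np.zeros((n_components,) + shape)
    maps[:, mask] = sources.T
    # temporal mixing back in concatenated-time space:
    # data ~ sources @ (ica.mixing_.T @ pca.components_)
    mixing = pca.components_.T @ ica.mixing_
    return ComponentMaps(maps=maps, mixing=mixing, mask=mask)


def select_language_component(
    maps: ComponentMaps, template: np.ndarray, floor: float = 0.2
) -> tuple[int, float, np.ndarray]:
    """Pick the component most spatially correlated with a network template.

    Returns (index, correlation, map), with the map sign-flipped so the
    correlation is positive.  Raises if no component reaches ``floor``.
    """
    if template.shape != maps.maps.shape[1:]:
        raise ValueError("template grid does not match component maps")
    tvec = template[maps.mask].astype(float)
    if tvec.std() == 0:
        raise ValueError("template has no variance inside the mask")
    rs = np.empty(maps.n_components)
    for i in range(maps.n_components):
        rs[i] = np.corrcoef(maps.maps[i][maps.mask], tvec)[0, 1]
    best = int(np.argmax(np.abs(rs)))
    r = float(rs[best])
    if abs(r) < floor:
        raise ValueError(
            f"no LN-like component: best spatial |r| = {abs(r):.3f} < {floor}"
        )
    comp = maps.maps[best] * np.sign(r)
    return best, abs(r), comp


@dataclass
class Cluster:
    label: int
    size: int
    peak: tuple[int, int, int]
    peak_value: float
    voxels: np.ndarray  # (n, 3) indices


def threshold_clusters(
    weight_map: np.ndarray,
    t_cerebral: float = 5.0,
    t_cerebellar: float = 3.0,
    cerebellar_mask: Optional[np.ndarray] = None,
    min_size: int = 10,
    connectivity: int = 26,
) -> list[Cluster]:
    """Threshold a component map and label suprathreshold clusters.

    Voxels inside ``cerebellar_mask`` use the (lower) cerebellar threshold.
    Clusters are connected components under 26-connectivity (6 behind the
    flag), discarded below ``min_size`` voxels.  Peaks are maxima, ties
    broken by lowest linear index.
    """
    if t_cerebral <= 0 or t_cerebellar <= 0:
        raise ValueError("thresholds must be positive")
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndi.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    above = weight_map > t_cerebral
    if cerebellar_mask is not None:
        if cerebellar_mask.shape != weight_map.shape:
            raise ValueError("cerebellar mask shape mismatch")
        above = np.where(cerebellar_mask, weight_map > t_cerebellar, above)
    labels, n = ndi.label(above, structure=structure)
    out: list[Cluster] = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) < min_size:
            continue
        vals = weight_map[vox[:, 0], vox[:, 1], vox[:, 2]]
        best = int(np.argmax(vals))  # first maximum = lowest linear index
        if np.sum(vals == vals[best]) > 1:
            logger.warning("peak tie in cluster %d; lowest linear index kept", lab)
        out.append(
            Cluster(
                label=lab,
                size=len(vox),
                peak=tuple(int(c) for c in vox[best]),
                peak_value=float(vals[best]),
                voxels=vox,
            )
        )
    return out


@dataclass
class SphereRoi:
    name: str
    center_mm: tuple[float, float, float]
    voxels: np.ndarray  # (n, 3) indices on the grid


def peak_rois(
    clusters: Sequence[Cluster],
    grid: GridSpec,
    radius_mm: float = 6.0,
    names: Optional[Sequence[str]] = None,
) -> list[SphereRoi]:
    """Place a sphere ROI of physical radius ``radius_mm`` on each cluster
    peak.  Spheres reaching outside the grid are truncated (logged)."""
    if not clusters:
        raise ValueError("need at least one cluster")
    if names is not None and len(names) != len(clusters):
        raise ValueError("one name per cluster required")
    out = []
    for i, cl in enumerate(clusters):
        center = grid.voxel_to_mm(cl.peak)
        vox = sphere_voxels(grid, center, radius_mm)
        full = sphere_voxels(
            GridSpec(
                tuple(s + 40 for s in grid.shape),
                grid.voxel_size_mm,
                tuple(o - 20 * v for o, v in zip(grid.origin_mm, grid.voxel_size_mm)),
            ),
            center,
            radius_mm,
        )
        if len(vox) < len(full):
            logger.warning(
                "ROI at %s truncated at the grid boundary (%d of %d voxels)",
                tuple(center), len(vox), len(full),
            )
        out.append(
            SphereRoi(
                name=names[i] if names else f"roi{i + 1}",
                center_mm=tuple(float(c) for c in center),
                voxels=vox,
            )
        )
    return out
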