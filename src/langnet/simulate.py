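"""Synthetic cohort generator encoding the core-periphery lesion model.

The generator emulates the study conditions of a glioma language-network
cohort: 10-node LN time series whose inter-node covariance depends on group
and tumor volume, plus small 4D phantom volumes with embedded spatial
component maps and ellipsoidal tumor masks.

Baseline (healthy-control) connectivity is left/right symmetric: moderate
within-hemisphere correlations, stronger homotopic correlations, weaker
heterotopic and midline correlations.  Lesion effects act additively on the
Fisher-z scale (so correlations stay inside (-1, 1) after mapping back):

* left-lesion groups (LFG, LTG; the network "core") lose a_dir * V on every
  edge incident to the lesioned subsystem and a_ind * V on all remaining
  edges — a global, volume-dependent attenuation;
* right-lesion groups (RFG, RTG; the "periphery") lose a_dir * V only on
  edges incident to the lesioned subsystem, and the left core triangle
  (lIFG-lMFG-lSTG) gains a compensatory b_con * (V - mean V): tumors larger
  than typical push contralesional core coupling up, smaller ones leave it
  near baseline, so the group mean stays at the healthy level while the
  volume slope is positive.

Ground truth (per-subject true edge z, true mNC) is retained for
parameter-recovery tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort_reference import GROUP_TO_SUBSYSTEM
from .connectivity import (
    EDGE_COLUMNS,
    EdgeVector,
    compute_mnc,
    edge_label,
    preprocess_timeseries,
)
from .grid import DEFAULT_PHANTOM_GRID, GridSpec
from .lesion import LesionMask, ellipsoid_mask
from .rois import (
    CANONICAL_ROI_SET,
    CORE_LEFT,
    HOMOTOPIC_PAIRS,
    NODE_ORDER,
    RoiSet,
    SUBSYSTEMS,
    edge_keys,
)

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "GroundTruth",
    "Cohort",
    "baseline_correlation",
    "build_group_covariance",
    "simulate_subject",
    "simulate_phantom",
    "generate_cohort",
    "true_edge_z",
    "nearest_positive_definite",
    "GROUP_TO_SUBSYSTEM",
]

logger = logging.getLogger(__name__)

_DEFAULT_SIZES = {"LFG": 27, "LTG": 26, "RFG": 29, "RTG": 27, "HC": 42}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the reference cohort's group sizes and plausible
    resting-state connectivity magnitudes; lesion-effect slopes are per cm^3
    of tumor volume on the Fisher-z scale.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_SIZES))
    n_timepoints: int = 200
    tr: float = 2.0
    r_within: float = 0.45
    r_homotopic: float = 0.50
    r_hetero: float = 0.25
    a_dir: float = 1.5e-3
    a_ind: float = 0.8e-3
    b_con: float = 0.65e-3
    tv_mean: float = 100.0
    tv_sd: float = 60.0
    tv_range: tuple[float, float] = (10.0, 300.0)
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r_within", "r_homotopic", "r_hetero"):
            r = getattr(self, name)
            if not -1.0 < r < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {r}")
        for name in ("a_dir", "a_ind", "b_con"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.group_sizes) - set(_DEFAULT_SIZES)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 subjects")
        if self.n_timepoints < 2 or self.tr <= 0 or self.noise_sd < 0:
            raise ValueError("invalid time-series settings")
        if not (0 < self.tv_range[0] < self.tv_range[1]):
            raise ValueError("invalid tumor-volume range")
        base = baseline_correlation(self)
        if np.linalg.eigvalsh(base).min() <= 0:
            raise ValueError("baseline correlation matrix is not positive definite")


def baseline_correlation(config: CohortConfig) -> np.ndarray:
    """Healthy-control 10x10 correlation matrix (left/right symmetric)."""
    n = len(NODE_ORDER)
    pos = {name: i for i, name in enumerate(NODE_ORDER)}
    left = {"lIFG", "lSTG", "lMFG", "lCPL"}
    right = {"rIFG", "rSTG", "rMFG", "rCPL"}
    homotopic = {frozenset(p) for p in HOMOTOPIC_PAIRS}
    mat = np.full((n, n), config.r_hetero)
    for a, b in edge_keys(NODE_ORDER):
        if frozenset((a, b)) in homotopic:
            r = config.r_homotopic
        elif {a, b} <= left or {a, b} <= right:
            r = config.r_within
        else:
            r = config.r_hetero
        mat[pos[a], pos[b]] = mat[pos[b], pos[a]] = r
    np.fill_diagonal(mat, 1.0)
    return mat


def nearest_positive_definite(mat: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped nearest-PD repair, rescaled to unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() > eps:
        return mat
    logger.warning(
        "correlation matrix repaired: smallest eigenvalue %.3g clipped to %.1g",
        vals.min(), eps,
    )
    vals = np.clip(vals, eps, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    if np.linalg.eigvalsh(fixed).min() <= 0:
        raise np.linalg.LinAlgError(
            f"matrix not positive definite after repair "
            f"(eigenvalue {np.linalg.eigvalsh(fixed).min():.3g})"
        )
    return fixed


def _direct_mask(subsystem: str) -> np.ndarray:
    """Boolean (10, 10): edges with >= 1 endpoint in the lesioned subsystem."""
    members = set(SUBSYSTEMS[subsystem])
    n = len(NODE_ORDER)
    inc = np.array([name in members for name in NODE_ORDER])
    mask = inc[:, None] | inc[None, :]
    np.fill_diagonal(mask, False)
    return mask


_LEFT_TRI_MASK = np.zeros((len(NODE_ORDER), len(NODE_ORDER)), dtype=bool)
for _a in CORE_LEFT:
    for _b in CORE_LEFT:
        if _a != _b:
            _LEFT_TRI_MASK[NODE_ORDER.index(_a), NODE_ORDER.index(_b)] = True


def build_group_covariance(
    config: CohortConfig, group: str, volume_cm3: float
) -> np.ndarray:
    """Node correlation matrix for one subject given group and tumor volume.

    HC returns the baseline unchanged.  Lesion effects are applied on the
    Fisher-z scale (see module docstring) and mapped back through tanh; the
    result is repaired to the nearest positive-definite correlation matrix
    if the additive effects broke definiteness.
    """
    base = baseline_correlation(config)
    if group == "HC":
        return base
    if group not in GROUP_TO_SUBSYSTEM:
        raise ValueError(f"unknown group {group!r}")
    if volume_cm3 < 0:
        raise ValueError("tumor volume must be >= 0")
    subsystem = GROUP_TO_SUBSYSTEM[group]
    off = ~np.eye(len(NODE_ORDER), dtype=bool)
    direct = _direct_mask(subsystem)
    z = np.zeros_like(base)
    z[off] = np.arctanh(base[off])
    if group in ("LFG", "LTG"):
        z[direct] -= config.a_dir * volume_cm3
        z[off & ~direct] -= config.a_ind * volume_cm3
    else:
        z[direct] -= config.a_dir * volume_cm3
        z[_LEFT_TRI_MASK] += config.b_con * (volume_cm3 - config.tv_mean)
    out = np.eye(len(NODE_ORDER))
    out[off] = np.tanh(z[off])
    return nearest_positive_definite(out)


def simulate_subject(
    cov: np.ndarray,
    n_timepoints: int,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator | int] = None,
    band: Optional[tuple[float, float]] = None,
    tr: float = 2.0,
) -> np.ndarray:
    """Draw one subject's (n_nodes, T) time series from a node covariance.

    Signals are multivariate normal with the given covariance; white
    measurement noise of SD ``noise_sd`` is added per node.  ``band``
    optionally band-limits the series (0.01-0.08 Hz mimics preprocessed
    BOLD).  Bit-identical under a fixed seed.
    """
    cov = np.asarray(cov, dtype=float)
    vals = np.linalg.eigvalsh(cov)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite (eigenvalue {vals.min():.3g})"
        )
    if n_timepoints < 20:
        warnings.warn(
            f"T={n_timepoints} < 20 time points: sample correlations will be "
            "unstable", stacklevel=2,
        )
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    chol = np.linalg.cholesky(cov)
    ts = chol @ gen.standard_normal((cov.shape[0], n_timepoints))
    if noise_sd > 0:
        ts = ts + noise_sd * gen.standard_normal(ts.shape)
    if band is not None:
        ts = preprocess_timeseries(ts, tr=tr, band=band, detrend=False)
    return ts


def true_edge_z(cov: np.ndarray, noise_sd: float = 0.0) -> pd.Series:
    """Population Fisher-z edge values implied by a node covariance.

    White measurement noise of SD sigma attenuates every observed
    correlation of unit-variance signals by 1 / (1 + sigma^2); the returned
    values are on that observable scale.
    """
    atten = 1.0 / (1.0 + noise_sd**2)
    pos = {n: i for i, n in enumerate(NODE_ORDER)}
    vals = {
        edge_label(a, b): float(np.arctanh(cov[pos[a], pos[b]] * atten))
        for a, b in edge_keys(NODE_ORDER)
    }
    return pd.Series(vals, index=list(EDGE_COLUMNS))


def _draw_tumor_volumes(
    n: int, mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal volumes with the given mean/SD, truncated by resampling."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, np.sqrt(sigma2), size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


@dataclass
class SubjectRecord:
    """One synthetic participant: label, tumor volume, ROI time series."""

    subject_id: str
    group: str
    subsystem: Optional[str]  # None for HC
    tumor_volume_cm3: float
    timeseries: np.ndarray  # (10, T)

    def edge_vector(self) -> EdgeVector:
        from .connectivity import edge_vector

        return edge_vector(self.timeseries)


@dataclass
class GroundTruth:
    """Retained simulation truth for parameter-recovery tests."""

    table: pd.DataFrame  # subject_id, group, subsystem, tumor_volume_cm3
    true_z: pd.DataFrame  # per-subject population edge z (45 columns)
    true_mnc: pd.DataFrame  # per-subject lfcw, rfcw, fcb, fcg
    group_z: dict[str, pd.Series]  # per-group edge z at the mean tumor volume


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectRecord]
    truth: GroundTruth

    def edge_table(self) -> pd.DataFrame:
        """Observed per-subject Fisher-z edges (subjects x 45)."""
        rows = {s.subject_id: s.edge_vector().values for s in self.subjects}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "subject_id"
        return df

    def subject_table(self) -> pd.DataFrame:
        return self.truth.table.copy()


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort, reproducibly from ``config.seed``."""
    master = np.random.SeedSequence(config.seed)
    vol_rng = np.random.default_rng(master.spawn(1)[0])
    subjects: list[SubjectRecord] = []
    truth_rows = []
    true_z_rows = {}
    mnc_rows = {}
    group_order = [g for g in ("LFG", "LTG", "RFG", "RTG", "HC") if config.group_sizes.get(g, 0) > 0]
    child_seeds = iter(master.spawn(sum(config.group_sizes[g] for g in group_order) + 1)[1:])
    for group in group_order:
        n = config.group_sizes[group]
        if group == "HC":
            volumes = np.zeros(n)
        else:
            volumes = _draw_tumor_volumes(
                n, config.tv_mean, config.tv_sd, *config.tv_range, vol_rng
            )
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            cov = build_group_covariance(config, group, volumes[i])
            ts = simulate_subject(
                cov,
                config.n_timepoints,
                noise_sd=config.noise_sd,
                rng=np.random.default_rng(next(child_seeds)),
                tr=config.tr,
            )
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    subsystem=GROUP_TO_SUBSYSTEM.get(group),
                    tumor_volume_cm3=float(volumes[i]),
                    timeseries=ts,
                )
            )
            truth_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "subsystem": GROUP_TO_SUBSYSTEM.get(group, ""),
                    "tumor_volume_cm3": float(volumes[i]),
                }
            )
            z = true_edge_z(cov, config.noise_sd)
            true_z_rows[sid] = z
            mnc_rows[sid] = compute_mnc(EdgeVector(z)).as_dict()
    table = pd.DataFrame(truth_rows).set_index("subject_id")
    true_z = pd.DataFrame.from_dict(true_z_rows, orient="index")
    true_mnc = pd.DataFrame.from_dict(mnc_rows, orient="index")
    group_z = {
        g: true_edge_z(
            build_group_covariance(config, g, 0.0 if g == "HC" else config.tv_mean),
            config.noise_sd,
        )
        for g in group_order
    }
    return Cohort(config, subjects, GroundTruth(table, true_z, true_mnc, group_z))


_SUBSYSTEM_CENTROIDS = {
    label: np.mean([CANONICAL_ROI_SET[n].coords for n in members], axis=0)
    for label, members in SUBSYSTEMS.items()
}


def simulate_phantom(
    timeseries: np.ndarray,
    roi_set: RoiSet = CANONICAL_ROI_SET,
    grid: GridSpec = DEFAULT_PHANTOM_GRID,
    tumor_volume_cm3: float = 0.0,
    subsystem: Optional[str] = None,
    blob_sigma_mm: float = 6.0,
    tumor_signal_scale: float = 0.2,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator | int] = None,
) -> tuple[np.ndarray, Optional[LesionMask]]:
    """Embed node time courses as Gaussian spatial blobs in a 4D phantom.

    Each node contributes a Gaussian blob (SD ``blob_sigma_mm``) centered on
    its peak coordinate whose time course is the node's signal; spatially
    white noise is added on top.  A tumor, if requested, is an ellipsoid of
    the given volume centered on the lesioned subsystem's centroid, with
    signal inside attenuated by ``tumor_signal_scale``.  Returns the
    (x, y, z, t) volume and the tumor mask (None for controls).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] != len(roi_set):
        raise ValueError(f"timeseries must be ({len(roi_set)}, T)")
    if min(grid.shape) < 24:
        raise ValueError("phantom grid must be at least 24 voxels per axis")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_t = ts.shape[1]
    weights = np.zeros((len(roi_set),) + grid.shape)
    axes = [
        np.asarray(grid.origin_mm[a]) + np.arange(grid.shape[a]) * grid.voxel_size_mm[a]
        for a in range(3)
    ]
    for i, node in enumerate(roi_set.nodes):
        d2 = (
            (axes[0][:, None, None] - node.x) ** 2
            + (axes[1][None, :, None] - node.y) ** 2
            + (axes[2][None, None, :] - node.z) ** 2
        )
        weights[i] = np.exp(-d2 / (2.0 * blob_sigma_mm**2))
        weights[i][d2 > (4.0 * blob_sigma_mm) ** 2] = 0.0

    mask: Optional[LesionMask] = None
    if tumor_volume_cm3 > 0:
        if subsystem not in _SUBSYSTEM_CENTROIDS:
            raise ValueError(
                f"tumor requested but subsystem {subsystem!r} is unknown"
            )
        mdata = ellipsoid_mask(grid, _SUBSYSTEM_CENTROIDS[subsystem], tumor_volume_cm3)
        mask = LesionMask(mdata, grid.voxel_size_mm, grid.origin_mm)

    flat_w = weights.reshape(len(roi_set), -1)
    if mask is not None:
        flat_w = flat_w * np.where(mask.data.reshape(-1) > 0, tumor_signal_scale, 1.0)
    vol = (flat_w.T @ ts).reshape(grid.shape + (n_t,))
    if noise_sd > 0:
        vol = vol + noise_sd * gen.standard_normal(vol.shape)
    return vol.astype(np.float32), mask
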