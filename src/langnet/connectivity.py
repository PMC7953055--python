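"""From ROI time series to edge-wise functional connectivity and the
hemispheric mean-network-connectivity (mNC) indices.

One subject's connectivity profile is the vector of all 45 pairwise Pearson
correlations between the 10 LN node signals, Fisher-z transformed.  The mNC
indices summarize the 15 edges among the six core homotopic nodes (bilateral
IFG, MFG, STG):

* lFCw / rFCw — mean z over the 3 edges within the left / right triangle,
* FCb — mean z over the 9 left-right cross edges,
* FCg — mean z over all 15 core edges, identically
  (3*lFCw + 3*rFCw + 9*FCb) / 15.

Edges touching the midline (SFG, precuneus) or cerebellar nodes are excluded
from mNC; a 10-node global variant (mean of all 45 edges) is available via
``scope="all10"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .grid import GridSpec, sphere_voxels
from .rois import (
    CORE_LEFT,
    CORE_RIGHT,
    N_EDGES,
    NODE_ORDER,
    RoiSet,
    edge_keys,
)
from .stats import fisher_z

__all__ = [
    "EDGE_COLUMNS",
    "edge_label",
    "EdgeVector",
    "MNCProfile",
    "preprocess_timeseries",
    "extract_roi_timeseries",
    "edge_vector",
    "compute_mnc",
    "ipsi_contra",
]


def edge_label(a: str, b: str) -> str:
    """Column label for an unordered node pair, endpoints in node order."""
    order = NODE_ORDER
    if order.index(a) > order.index(b):
        a, b = b, a
    return f"{a}--{b}"


EDGE_COLUMNS: tuple[str, ...] = tuple(edge_label(a, b) for a, b in edge_keys())


@dataclass(frozen=True)
class EdgeVector:
    """The 45 Fisher-z edge values of one subject, keyed by node pair."""

    values: pd.Series  # index = EDGE_COLUMNS

    def __post_init__(self) -> None:
        if len(self.values) != N_EDGES:
            raise ValueError(f"expected {N_EDGES} edges, got {len(self.values)}")
        if list(self.values.index) != list(EDGE_COLUMNS):
            raise ValueError("edge index must match the canonical 45 node pairs")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("edge values must be finite")

    def get(self, a: str, b: str) -> float:
        return float(self.values[edge_label(a, b)])


@dataclass(frozen=True)
class MNCProfile:
    """Per-subject mean network connectivity (Fisher-z units)."""

    lfcw: float
    rfcw: float
    fcb: float
    fcg: float
    ipsi: Optional[float] = None
    contra: Optional[float] = None

    def as_dict(self) -> dict:
        d = {"lfcw": self.lfcw, "rfcw": self.rfcw, "fcb": self.fcb, "fcg": self.fcg}
        if self.ipsi is not None:
            d["ipsi_fcw"] = self.ipsi
            d["contra_fcw"] = self.contra
        return d


def preprocess_timeseries(
    ts: np.ndarray,
    tr: float,
    band: Optional[tuple[float, float]] = (0.01, 0.08),
    confounds: Optional[np.ndarray] = None,
    detrend: bool = True,
) -> np.ndarray:
    """Linear detrend, optional confound regression, and zero-phase
    band-pass filtering of node time series.

    Parameters
    ----------
    ts : (n_rois, n_timepoints) array.
    tr : repetition time in seconds (sampling interval).
    band : (low, high) pass band in Hz, or None to skip filtering.  The
        filter is a 4th-order Butterworth applied forward-backward.
    confounds : optional (n_timepoints, n_regressors) nuisance matrix,
        removed by least squares (an intercept is always included).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be 2-D (n_rois, n_timepoints)")
    if tr <= 0:
        raise ValueError("tr must be positive")
    out = ts.copy()
    if detrend:
        out = _sig.detrend(out, axis=1, type="linear")
    if confounds is not None:
        conf = np.asarray(confounds, dtype=float)
        if conf.shape[0] != out.shape[1]:
            raise ValueError("confounds must have one row per time point")
        design = np.column_stack([np.ones(conf.shape[0]), conf])
        beta, *_ = np.linalg.lstsq(design, out.T, rcond=None)
        out = out - (design @ beta).T
    if band is not None:
        low, high = band
        nyq = 0.5 / tr
        if not (0.0 < low < high):
            raise ValueError("band must satisfy 0 < low < high")
        if high >= nyq:
            raise ValueError(
                f"band high edge {high} Hz is at or above Nyquist {nyq} Hz"
            )
        b, a = _sig.butter(4, [low / nyq, high / nyq], btype="band")
        out = _sig.filtfilt(b, a, out, axis=1)
    return out


def extract_roi_timeseries(
    volume4d: np.ndarray,
    roi_set: RoiSet,
    grid: GridSpec,
) -> np.ndarray:
    """Mean signal over each sphere ROI's voxels for every frame.

    Returns an (n_rois, n_timepoints) array in node order.  Spheres are
    truncated at the grid boundary; an ROI with no voxels on the grid is an
    error naming the node.
    """
    vol = np.asarray(volume4d)
    if vol.ndim != 4:
        raise ValueError("volume4d must be 4-D (x, y, z, t)")
    if vol.shape[:3] != grid.shape:
        raise ValueError("volume shape does not match the grid spec")
    out = np.empty((len(roi_set), vol.shape[3]))
    for i, node in enumerate(roi_set.nodes):
        vox = sphere_voxels(grid, node.coords, roi_set.radius_mm)
        if vox.shape[0] == 0:
            raise ValueError(f"ROI {node.name!r} has no voxels on this grid")
        out[i] = vol[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0)
    return out


def edge_vector(ts: np.ndarray, names: Sequence[str] = NODE_ORDER) -> EdgeVector:
    """All 45 pairwise Pearson correlations, Fisher-z transformed.

    ``ts`` is (n_rois, n_timepoints) in node order.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] != len(names):
        raise ValueError(f"ts must be ({len(names)}, T)")
    if ts.shape[1] < 4:
        raise ValueError("need at least 4 time points")
    sds = ts.std(axis=1)
    for name, sd in zip(names, sds):
        if sd == 0.0:
            raise ValueError(f"zero-variance time series for node {name!r}")
    corr = np.corrcoef(ts)
    assert np.allclose(np.diag(corr), 1.0)
    pos = {n: i for i, n in enumerate(names)}
    vals = {}
    for a, b in edge_keys(names):
        r = float(corr[pos[a], pos[b]])
        vals[edge_label(a, b)] = fisher_z(r, label=edge_label(a, b))
    return EdgeVector(pd.Series(vals, index=list(EDGE_COLUMNS)))


_LEFT_TRI = tuple(
    edge_label(a, b) for a, b in edge_keys(NODE_ORDER) if a in CORE_LEFT and b in CORE_LEFT
)
_RIGHT_TRI = tuple(
    edge_label(a, b)
    for a, b in edge_keys(NODE_ORDER)
    if a in CORE_RIGHT and b in CORE_RIGHT
)
_CROSS = tuple(
    edge_label(a, b)
    for a, b in edge_keys(NODE_ORDER)
    if (a in CORE_LEFT) != (b in CORE_LEFT) and {a, b} <= set(CORE_LEFT + CORE_RIGHT)
)


def compute_mnc(ev: EdgeVector, scope: str = "core6") -> MNCProfile:
    """Reduce a subject's edge vector to the four mNC indices.

    ``scope="core6"`` (default) computes FCg over the 15 edges among the six
    core homotopic nodes; ``scope="all10"`` averages all 45 edges instead.
    """
    if scope not in ("core6", "all10"):
        raise ValueError(f"unknown mNC scope {scope!r}")
    v = ev.values
    lfcw = float(v[list(_LEFT_TRI)].mean())
    rfcw = float(v[list(_RIGHT_TRI)].mean())
    fcb = float(v[list(_CROSS)].mean())
    if scope == "core6":
        fcg = (3.0 * lfcw + 3.0 * rfcw + 9.0 * fcb) / 15.0
    else:
        fcg = float(v.mean())
    return MNCProfile(lfcw=lfcw, rfcw=rfcw, fcb=fcb, fcg=fcg)


def ipsi_contra(profile: MNCProfile, lesion_side: str) -> MNCProfile:
    """Relabel within-hemisphere indices relative to the lesioned side.

    Left lesion: ipsi = lFCw, contra = rFCw; right lesion mirrored.
    Healthy controls have no lesion side — pass of ``None`` is an error.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError(
            f"lesion side must be 'left' or 'right', got {lesion_side!r} "
            "(ipsi/contra are undefined for controls)"
        )
    if lesion_side == "left":
        return replace(profile, ipsi=profile.lfcw, contra=profile.rfcw)
    return replace(profile, ipsi=profile.rfcw, contra=profile.lfcw)
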