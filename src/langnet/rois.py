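"""Language-network node definitions: the canonical 10-node ROI set and the
four-lesion-subsystem atlas.

The language network (LN) studied here consists of ten modules identified by
group spatial ICA of resting-state fMRI: bilateral inferior frontal gyri
(IFG), middle frontal gyri (MFG) and superior temporal gyri (STG), a midline
superior frontal cluster, the precuneus, and two cerebellar posterior-lobe
clusters.  Sphere ROIs of 6 mm radius are placed on each module's peak voxel
in MNI space; all pairwise Pearson correlations between ROI mean signals give
the 45-edge functional-connectivity profile of one subject.

Tumours are grouped into four lesion subsystems: left frontal (LF = lIFG +
lMFG), left temporal (LT = lSTG), and the right homologues RF and RT.
Midline and cerebellar nodes belong to no subsystem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "RoiNode",
    "RoiSet",
    "SubsystemAtlas",
    "CANONICAL_ROI_SET",
    "DEFAULT_ATLAS",
    "NODE_ORDER",
    "CORE_LEFT",
    "CORE_RIGHT",
    "CORE_NODES",
    "LEFT_NODES",
    "RIGHT_NODES",
    "MIDLINE_NODES",
    "HOMOTOPIC_PAIRS",
    "SUBSYSTEMS",
    "SUBSYSTEM_LABELS",
    "edge_key",
    "edge_keys",
    "N_EDGES",
    "node_subsystem",
]


@dataclass(frozen=True)
class RoiNode:
    """One LN module: name, MNI peak coordinate (mm), module size (voxels)."""

    name: str
    x: float
    y: float
    z: float
    size_voxels: int
    peak_t: float

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class RoiSet:
    """An ordered collection of sphere ROIs sharing one radius."""

    nodes: tuple[RoiNode, ...]
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("sphere radius must be positive")
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names in RoiSet")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def coords(self) -> np.ndarray:
        """(n_nodes, 3) array of MNI peak coordinates in mm."""
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, name: str) -> RoiNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "radius_mm": self.radius_mm,
            "nodes": [vars(n) for n in self.nodes],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSet":
        payload = json.loads(Path(path).read_text())
        nodes = tuple(RoiNode(**n) for n in payload["nodes"])
        return cls(nodes=nodes, radius_mm=payload["radius_mm"])

    def to_tsv(self, path: str | Path) -> None:
        lines = ["name\tx\ty\tz\tsize_voxels"]
        for n in self.nodes:
            lines.append(f"{n.name}\t{n.x:g}\t{n.y:g}\t{n.z:g}\t{n.size_voxels}")
        Path(path).write_text("\n".join(lines) + "\n")


# Canonical ROI set: ICA-derived LN module peaks in MNI space (mm), module
# sizes in 3 mm isotropic voxels, and the peak-level T score of each module.
CANONICAL_ROI_SET = RoiSet(
    nodes=(
        RoiNode("lIFG", -51, 21, -9, 218, 10.93),
        RoiNode("lSTG", -57, -57, 12, 955, 16.27),
        RoiNode("lMFG", -45, 3, 48, 136, 11.30),
        RoiNode("rIFG", 54, 24, -6, 127, 8.26),
        RoiNode("rSTG", 60, -51, 12, 1149, 19.82),
        RoiNode("rMFG", 45, 9, 45, 104, 9.86),
        RoiNode("l/rSFG", -3, 12, 57, 109, 7.85),
        RoiNode("l/rPC", 0, -57, 39, 133, 8.39),
        RoiNode("lCPL", -21, -78, -39, 92, 3.47),
        RoiNode("rCPL", 21, -81, -42, 43, 3.17),
    ),
    radius_mm=6.0,
)

NODE_ORDER: tuple[str, ...] = CANONICAL_ROI_SET.names

CORE_LEFT: tuple[str, ...] = ("lIFG", "lMFG", "lSTG")
CORE_RIGHT: tuple[str, ...] = ("rIFG", "rMFG", "rSTG")
CORE_NODES: tuple[str, ...] = CORE_LEFT + CORE_RIGHT

LEFT_NODES: tuple[str, ...] = ("lIFG", "lSTG", "lMFG", "lCPL")
RIGHT_NODES: tuple[str, ...] = ("rIFG", "rSTG", "rMFG", "rCPL")
MIDLINE_NODES: tuple[str, ...] = ("l/rSFG", "l/rPC")

HOMOTOPIC_PAIRS: tuple[tuple[str, str], ...] = (
    ("lIFG", "rIFG"),
    ("lMFG", "rMFG"),
    ("lSTG", "rSTG"),
    ("lCPL", "rCPL"),
)

SUBSYSTEM_LABELS: tuple[str, ...] = ("LF", "LT", "RF", "RT")

SUBSYSTEMS: dict[str, tuple[str, ...]] = {
    "LF": ("lIFG", "lMFG"),
    "LT": ("lSTG",),
    "RF": ("rIFG", "rMFG"),
    "RT": ("rSTG",),
}


def node_subsystem(name: str) -> Optional[str]:
    """Subsystem label of a node, or None for midline/cerebellar nodes."""
    if name not in NODE_ORDER:
        raise KeyError(f"unknown node name: {name!r}")
    for label, members in SUBSYSTEMS.items():
        if name in members:
            return label
    return None


def edge_key(a: str, b: str, order: Iterable[str] = NODE_ORDER) -> tuple[str, str]:
    """Canonical unordered pair: endpoints sorted by node order."""
    order = list(order)
    if a == b:
        raise ValueError(f"self-edge: {a!r}")
    for n in (a, b):
        if n not in order:
            raise KeyError(f"unknown node name: {n!r}")
    return (a, b) if order.index(a) < order.index(b) else (b, a)


def edge_keys(names: Iterable[str] = NODE_ORDER) -> tuple[tuple[str, str], ...]:
    """All unordered node pairs in canonical order."""
    return tuple(combinations(tuple(names), 2))


N_EDGES: int = len(edge_keys())  # C(10, 2) = 45


@dataclass
class SubsystemAtlas:
    """Node->subsystem map, with optional voxel parcels for mask assignment.

    ``parcels`` maps a subsystem label to a binary 3D voxel grid; parcels
    must be pairwise disjoint and share one grid shape.
    """

    node_map: Mapping[str, Optional[str]] = field(
        default_factory=lambda: {n: node_subsystem(n) for n in NODE_ORDER}
    )
    parcels: Optional[dict[str, np.ndarray]] = None
    voxel_size_mm: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        for node, label in self.node_map.items():
            if label is not None and label not in SUBSYSTEM_LABELS:
                raise ValueError(f"unknown subsystem {label!r} for node {node!r}")
        if self.parcels is not None:
            shapes = {p.shape for p in self.parcels.values()}
            if len(shapes) > 1:
                raise ValueError("subsystem parcels must share one grid shape")
            total = sum((p > 0).astype(int) for p in self.parcels.values())
            if np.any(total > 1):
                raise ValueError("subsystem parcels must be disjoint")

    def subsystem_of(self, node: str) -> Optional[str]:
        if node not in self.node_map:
            raise KeyError(f"unknown node name: {node!r}")
        return self.node_map[node]

    def nodes_in(self, subsystem: str) -> tuple[str, ...]:
        return tuple(n for n, s in self.node_map.items() if s == subsystem)


DEFAULT_ATLAS = SubsystemAtlas()
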