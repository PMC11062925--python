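"""Core domain types: fluid, vessel trees, LV meshes and clinical targets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class FluidProperties:
    """Blood rheology in CGS units.

    viscosity : dynamic viscosity [Poise = dyn.s/cm^2]
    density   : [g/cm^3]
    """

    viscosity: float = 0.04
    density: float = 1.06

    def __post_init__(self):
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("fluid properties must be strictly positive")


@dataclass
class VesselSegment:
    """A straight cylindrical vessel segment in a branching tree."""

    id: int
    parent_id: Optional[int]
    p0: np.ndarray  # proximal endpoint [cm]
    p1: np.ndarray  # distal endpoint [cm]
    radius: float  # [cm]
    origin_tag: str = "synthetic"  # {"image_based", "synthetic"}
    perfuses_lv: bool = True

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if self.p0.shape != (3,) or self.p1.shape != (3,):
            raise ValueError("segment endpoints must be 3D points")
        if self.radius <= 0:
            raise ValueError(f"segment {self.id}: radius must be > 0")
        if self.origin_tag not in ("image_based", "synthetic"):
            raise ValueError(f"segment {self.id}: bad origin_tag {self.origin_tag!r}")
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: zero-length segment")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))


class VesselTree:
    """Directed branching geometry: segments with parent links, one root.

    Outlets are exactly the leaf segments, kept in a stable (sorted-id)
    order.  Structure is validated on construction: connected, acyclic,
    no orphans.
    """

    def __init__(self, segments: Sequence[VesselSegment], root_id: int):
        self.segments: Dict[int, VesselSegment] = {s.id: s for s in segments}
        if len(self.segments) != len(segments):
            raise ValueError("duplicate segment ids")
        if root_id not in self.segments:
            raise ValueError(f"root id {root_id} not among segments")
        self.root_id = root_id
        self._children: Dict[int, List[int]] = {sid: [] for sid in self.segments}
        for s in segments:
            if s.id == root_id:
                if s.parent_id is not None:
                    raise ValueError("root segment must have parent_id=None")
                continue
            if s.parent_id is None:
                raise ValueError(f"non-root segment {s.id} has no parent")
            if s.parent_id not in self.segments:
                raise ValueError(f"segment {s.id} references missing parent {s.parent_id}")
            self._children[s.parent_id].append(s.id)
        for sid in self._children:
            self._children[sid].sort()
        # reachability check -> connected and acyclic (parent-link forest + one root)
        seen = set()
        stack = [root_id]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise ValueError("cycle detected in vessel tree")
            seen.add(sid)
            stack.extend(self._children[sid])
        if seen != set(self.segments):
            orphans = sorted(set(self.segments) - seen)
            raise ValueError(f"orphan segments not reachable from root: {orphans}")

    # -- topology -----------------------------------------------------------

    def children(self, sid: int) -> List[int]:
        return list(self._children[sid])

    @property
    def outlet_ids(self) -> List[int]:
        return sorted(sid for sid, ch in self._children.items() if not ch)

    @property
    def lv_outlet_ids(self) -> List[int]:
        return [sid for sid in self.outlet_ids if self.segments[sid].perfuses_lv]

    def path_to_root(self, sid: int) -> List[int]:
        """Segment ids from ``sid`` up to and including the root."""
        path = [sid]
        while self.segments[path[-1]].parent_id is not None:
            path.append(self.segments[path[-1]].parent_id)
        return path

    def subtree_ids(self, sid: int) -> List[int]:
        out, stack = [], [sid]
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(self._children[s])
        return out

    def topo_order(self) -> List[int]:
        """Root-first order (parents before children)."""
        order, stack = [], [self.root_id]
        while stack:
            sid = stack.pop()
            order.append(sid)
            stack.extend(reversed(self._children[sid]))
        return order

    def total_volume(self) -> float:
        """Sum of cylindrical segment volumes [mL]."""
        return float(
            sum(np.pi * s.radius**2 * s.length for s in self.segments.values())
        )

    def copy(self) -> "VesselTree":
        segs = [
            VesselSegment(s.id, s.parent_id, s.p0.copy(), s.p1.copy(), s.radius,
                          s.origin_tag, s.perfuses_lv)
            for s in self.segments.values()
        ]
        return VesselTree(segs, self.root_id)


@dataclass
class LVMesh:
    """Tetrahedral LV volume mesh with an optional nodal MBF field.

    nodes     : (N, 3) float coordinates [cm]
    tets      : (M, 4) int connectivity (positively oriented)
    nodal_mbf : optional (N,) MBF [mL/min/100 mL]
    """

    nodes: np.ndarray
    tets: np.ndarray
    nodal_mbf: Optional[np.ndarray] = None

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (N, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be (M, 4)")
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= len(self.nodes):
            raise ValueError("tet connectivity out of range")
        vols = self.tet_volumes()
        if np.any(vols <= 0):
            raise ValueError("all tets must be positively oriented (volume > 0)")
        if self.nodal_mbf is not None:
            self.nodal_mbf = np.asarray(self.nodal_mbf, dtype=float)
            if self.nodal_mbf.shape != (len(self.nodes),):
                raise ValueError("nodal_mbf length must match node count")
            if np.any(self.nodal_mbf < 0):
                raise ValueError("nodal_mbf must be non-negative")

    def tet_volumes(self) -> np.ndarray:
        """Signed tet volumes [mL]; positive for valid orientation."""
        p = self.nodes[self.tets]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    @property
    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def node_control_volumes(self) -> np.ndarray:
        """Node-centred control volumes: each tet contributes V/4 per vertex."""
        vols = self.tet_volumes() / 4.0
        cv = np.zeros(len(self.nodes))
        for k in range(4):
            np.add.at(cv, self.tets[:, k], vols)
        return cv


@dataclass
class ClinicalTargets:
    """Measured cardiac-function targets in clinical units."""

    sbp: float  # systolic BP [mmHg]
    dbp: float  # diastolic BP [mmHg]
    stroke_volume: float  # [mL]
    ejection_fraction: float  # [-]
    cardiac_output: Optional[float] = None  # [L/min]
    edv: Optional[float] = None  # [mL]
    esv: Optional[float] = None  # [mL]
    heart_rate: float = 60.0  # [beats/min]
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.sbp > self.dbp > 0):
            raise ValueError("require sbp > dbp > 0")
        if not (0 < self.ejection_fraction < 1):
            raise ValueError("require 0 < EF < 1")

    @property
    def mean_pressure(self) -> float:
        """Mean aortic pressure estimate (DBP + pulse/3) [mmHg]."""
        return self.dbp + (self.sbp - self.dbp) / 3.0

    @property
    def cardiac_output_mls(self) -> float:
        """Cardiac output [mL/s]; from CO if given, else SV x HR."""
        if self.cardiac_output is not None:
            return self.cardiac_output * 1000.0 / 60.0
        return self.stroke_volume * self.heart_rate / 60.0

    def to_dict(self) -> dict:
        d = {
            "sbp": self.sbp,
            "dbp": self.dbp,
            "stroke_volume": self.stroke_volume,
            "ejection_fraction": self.ejection_fraction,
            "heart_rate": self.heart_rate,
        }
        for k in ("cardiac_output", "edv", "esv"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicalTargets":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
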