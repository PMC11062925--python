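"""Synthetic vascular tree growth by constrained constructive optimization.

One independent binary tree is grown per perfusion territory.  Terminals
carry equal flow; radii follow the gamma-law bifurcation rule
``r_child = r_parent * (Q_child / Q_parent)**(1/gamma)``; each new terminal
is connected at the volume-minimizing bifurcation point among the k nearest
existing segments.  Also provides the outlet-driven radius-scaling
(dilate/constrict) machinery used by the flow-tuning loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .core_model import LVMesh, VesselSegment, VesselTree
from .territories import PerfusionTerritoryMap

log = logging.getLogger(__name__)


@dataclass
class CCOConfig:
    total_terminals: int = 500
    murray_gamma: float = 3.0
    candidate_attempts: int = 10
    neighbor_count: int = 5
    seed: int = 0
    min_terminal_radius: float = 0.015  # ~300 um diameter floor
    spacing_coeff: float = 0.6

    def __post_init__(self):
        if self.total_terminals < 1:
            raise ValueError("total_terminals must be >= 1")
        if self.murray_gamma <= 0:
            raise ValueError("murray_gamma must be > 0")


def allocate_terminals(volumes: Sequence[float], total_terminals: int) -> np.ndarray:
    """Largest-remainder apportionment of terminals proportional to volume.

    Every territory receives at least one terminal and the counts sum to
    ``total_terminals`` exactly.
    """
    volumes = np.asarray(volumes, dtype=float)
    n = len(volumes)
    if np.any(volumes <= 0):
        raise ValueError("territory volumes must be > 0")
    if total_terminals < n:
        raise ValueError(f"need at least {n} terminals for {n} territories")
    quota = volumes / volumes.sum() * (total_terminals - n)
    counts = np.floor(quota).astype(int)
    rem = total_terminals - n - counts.sum()
    frac = quota - np.floor(quota)
    # deterministic ranking: largest remainder, ties to lowest index
    order = np.lexsort((np.arange(n), -frac))
    counts[order[:rem]] += 1
    return counts + 1


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

class _GrowingTree:
    """Mutable array-backed binary tree used during CCO insertion."""

    def __init__(self, root_point: np.ndarray, first_terminal: np.ndarray,
                 root_radius: float, gamma: float, min_radius: float):
        self.p0 = [np.asarray(root_point, float)]
        self.p1 = [np.asarray(first_terminal, float)]
        self.parent: List[Optional[int]] = [None]
        self.children: List[List[int]] = [[]]
        self.gamma = gamma
        self.root_radius = root_radius
        self.min_radius = min_radius
        self.radius = [root_radius]
        self.n_leaves_below = [1]
        self.clamped = 0

    def __len__(self):
        return len(self.p0)

    def seg_length(self, i: int) -> float:
        return float(np.linalg.norm(self.p1[i] - self.p0[i]))

    def point_segment_dist(self, x: np.ndarray, i: int) -> float:
        a, b = self.p0[i], self.p1[i]
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((x - a) @ ab / denom, 0.0, 1.0))
        return float(np.linalg.norm(x - (a + t * ab)))

    def insert(self, seg: int, bif_point: np.ndarray, terminal: np.ndarray) -> None:
        """Split ``seg`` at ``bif_point`` and hang a new terminal there."""
        bif_point = np.asarray(bif_point, float)
        # distal half of the split segment inherits the children
        distal = len(self.p0)
        self.p0.append(bif_point.copy())
        self.p1.append(self.p1[seg])
        self.parent.append(seg)
        self.children.append(self.children[seg])
        self.radius.append(self.radius[seg])
        self.n_leaves_below.append(self.n_leaves_below[seg])
        for c in self.children[distal]:
            self.parent[c] = distal
        # new terminal
        term = len(self.p0)
        self.p0.append(bif_point.copy())
        self.p1.append(np.asarray(terminal, float))
        self.parent.append(seg)
        self.children.append([])
        self.radius.append(self.min_radius)
        self.n_leaves_below.append(1)
        # shrink original segment to its proximal half
        self.p1[seg] = bif_point.copy()
        self.children[seg] = [distal, term]
        # update leaf counts up the tree
        j: Optional[int] = seg
        while j is not None:
            self.n_leaves_below[j] += 1
            j = self.parent[j]
        self.update_radii()

    def update_radii(self) -> None:
        """Top-down gamma-law radii from equal terminal flows."""
        stack = [0]
        self.radius[0] = self.root_radius
        inv_g = 1.0 / self.gamma
        while stack:
            i = stack.pop()
            for c in self.children[i]:
                r = self.radius[i] * (self.n_leaves_below[c] / self.n_leaves_below[i]) ** inv_g
                if r < self.min_radius:
                    r = self.min_radius
                    self.clamped += 1
                self.radius[c] = min(r, self.radius[i])
                stack.append(c)

    def total_volume(self) -> float:
        return float(sum(np.pi * self.radius[i] ** 2 * self.seg_length(i)
                         for i in range(len(self))))

    def to_vessel_tree(self, perfuses_lv: bool = True) -> VesselTree:
        segs = [
            VesselSegment(i, self.parent[i], self.p0[i], self.p1[i], self.radius[i],
                          "synthetic", perfuses_lv)
            for i in range(len(self))
        ]
        return VesselTree(segs, 0)


def connection_cost(tree: _GrowingTree, seg: int, x: np.ndarray,
                    terminal: np.ndarray, q_term: float = 1.0) -> float:
    """Local vascular volume of the trifurcated connection at point x.

    The split segment keeps its radius above the bifurcation; the two
    daughters take gamma-law radii from the post-insertion flow split.
    Degenerate geometry is penalized.
    """
    a, b = tree.p0[seg], tree.p1[seg]
    l_prox = float(np.linalg.norm(x - a))
    l_dist = float(np.linalg.norm(b - x))
    l_term = float(np.linalg.norm(terminal - x))
    if min(l_prox, l_dist, l_term) < 1e-4:
        return 1e12
    q_dist = tree.n_leaves_below[seg] * q_term
    q_tot = q_dist + q_term
    r_par = tree.radius[seg]
    inv_g = 1.0 / tree.gamma
    r_dist = r_par * (q_dist / q_tot) ** inv_g
    r_term = r_par * (q_term / q_tot) ** inv_g
    return float(np.pi * (r_par**2 * l_prox + r_dist**2 * l_dist + r_term**2 * l_term))


def optimize_bifurcation(tree: _GrowingTree, seg: int, terminal: np.ndarray,
                         maxiter: int = 60) -> np.ndarray:
    """Nelder-Mead search for the volume-minimizing bifurcation point.

    Starts at the segment midpoint; the result never costs more than the
    naive midpoint connection.
    """
    x0 = 0.5 * (tree.p0[seg] + tree.p1[seg])
    res = minimize(
        lambda x: connection_cost(tree, seg, x, terminal),
        x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-10},
    )
    if connection_cost(tree, seg, res.x, terminal) <= connection_cost(tree, seg, x0, terminal):
        return res.x
    return x0


def grow_tree(territory_points: np.ndarray, root_point: np.ndarray,
              root_radius: float, root_flow: float, n_terminals: int,
              config: CCOConfig, territory_volume: Optional[float] = None,
              rng: Optional[np.random.Generator] = None) -> VesselTree:
    """Grow a binary tree with exactly ``n_terminals`` leaves.

    territory_points : (P, 3) candidate terminal locations inside the territory
    root_point       : entry point (epicardial outlet position)
    root_flow        : flow carried by the tree [mL/s]; terminals split it equally
    """
    territory_points = np.asarray(territory_points, dtype=float)
    if len(territory_points) == 0:
        raise ValueError("territory has no candidate points")
    if n_terminals < 1:
        raise ValueError("n_terminals must be >= 1")
    rng = rng or np.random.default_rng(config.seed)
    if territory_volume is None:
        span = territory_points.max(axis=0) - territory_points.min(axis=0)
        territory_volume = float(np.prod(np.maximum(span, 1e-3)))

    # first terminal: the point farthest from the root (deterministic)
    d0 = np.linalg.norm(territory_points - root_point, axis=1)
    first = int(np.argmax(d0))
    tree = _GrowingTree(root_point, territory_points[first],
                        root_radius, config.murray_gamma, config.min_terminal_radius)
    used = {first}

    q_term = root_flow / n_terminals
    while tree.n_leaves_below[0] < n_terminals:
        n_cur = tree.n_leaves_below[0]
        d_thresh = config.spacing_coeff * (territory_volume / max(n_cur, 1)) ** (1.0 / 3.0)
        pos = None
        relaxations = 0
        while pos is None:
            for _ in range(config.candidate_attempts):
                idx = int(rng.integers(len(territory_points)))
                cand = territory_points[idx]
                if idx in used:
                    cand = cand + rng.normal(0.0, 0.05, size=3)
                dmin = min(tree.point_segment_dist(cand, i) for i in range(len(tree)))
                if dmin >= d_thresh:
                    pos = cand
                    used.add(idx)
                    break
            else:
                d_thresh *= 0.9
                relaxations += 1
                if relaxations > 60:
                    raise RuntimeError("terminal placement failed to converge")
        if relaxations:
            log.debug("relaxed spacing %d time(s) for terminal %d", relaxations, n_cur + 1)

        # k nearest segments by point-to-segment distance
        dists = np.array([tree.point_segment_dist(pos, i) for i in range(len(tree))])
        k = min(config.neighbor_count, len(tree))
        cand_segs = np.argsort(dists)[:k]
        best_cost, best = np.inf, None
        for seg in cand_segs:
            x = optimize_bifurcation(tree, int(seg), pos)
            c = connection_cost(tree, int(seg), x, pos, q_term)
            if c < best_cost:
                best_cost, best = c, (int(seg), x)
        tree.insert(best[0], best[1], pos)

    return tree.to_vessel_tree()


def terminal_flows(tree: VesselTree, root_flow: float) -> Dict[int, float]:
    """Equal per-terminal flows for a grown tree [mL/s]."""
    outs = tree.outlet_ids
    return {sid: root_flow / len(outs) for sid in outs}


# ---------------------------------------------------------------------------
# radius scaling
# ---------------------------------------------------------------------------

@dataclass
class RadiusScalePlan:
    """Per-segment scale factors after outlet->root max-propagation."""

    scales: Dict[int, float]


def propagate_scales(tree: VesselTree, outlet_scales: Dict[int, float]) -> RadiusScalePlan:
    """Propagate outlet scale factors up the tree.

    Each parent takes the maximum of its children's scale factors.  The
    propagation is idempotent: re-propagating the resulting leaf scales
    reproduces the same plan.
    """
    for sid, a in outlet_scales.items():
        if a <= 0:
            raise ValueError(f"non-positive scale factor for outlet {sid}")
    missing = set(tree.outlet_ids) - set(outlet_scales)
    if missing:
        raise ValueError(f"missing scale factors for outlets {sorted(missing)}")
    scales: Dict[int, float] = {}
    for sid in reversed(tree.topo_order()):
        ch = tree.children(sid)
        if not ch:
            scales[sid] = float(outlet_scales[sid])
        else:
            scales[sid] = max(scales[c] for c in ch)
    return RadiusScalePlan(scales)


def apply_radius_scaling(tree: VesselTree, outlet_scales: Dict[int, float]) -> VesselTree:
    """Dilate/constrict a tree from per-outlet scale factors.

    Leaf scales are as given; parents take the max of their daughters; the
    scaled radius of every vessel is capped by its (scaled) parent radius so
    the morphometric ordering is preserved.  Returns a new tree.
    """
    plan = propagate_scales(tree, outlet_scales)
    new = tree.copy()
    new_radius: Dict[int, float] = {}
    for sid in new.topo_order():
        s = new.segments[sid]
        r = plan.scales[sid] * s.radius
        if s.parent_id is not None:
            r = min(r, new_radius[s.parent_id])
        new_radius[sid] = r
        s.radius = r
    return new
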