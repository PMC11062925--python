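"""Seed-reproducible synthetic patients.

Generates an analytic half-ellipsoid LV shell mesh, an epicardial coronary
tree with LV-perfusing outlets on the epicardial surface, ground-truth
per-outlet flows (a dispersed perturbation of the diameter-law split), a
nodal MBF field consistent with those flows, and clinical targets taken
from a bundled reference-patient table.  Everything is deterministic for a fixed
seed, so downstream stages are testable without any imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core_model import ClinicalTargets, LVMesh, VesselSegment, VesselTree
from .core_model.units import flow_density_to_mbf_clinical
from . import territories as terr

#: Bundled reference-patient clinical summaries: (sbp, dbp, SV [mL], LVEF).
PATIENT_TABLE: Dict[int, Tuple[float, float, float, float]] = {
    1: (132.0, 69.0, 66.3, 0.68),
    2: (137.0, 73.0, 40.4, 0.65),
    3: (135.0, 80.0, 67.2, 0.60),
    4: (156.0, 72.0, 58.4, 0.60),
    5: (109.0, 75.0, 80.4, 0.60),
    6: (162.0, 65.0, 52.1, 0.63),
}


def table_targets(patient: int) -> ClinicalTargets:
    """Clinical targets for one of the bundled reference-patient rows."""
    sbp, dbp, sv, ef = PATIENT_TABLE[patient]
    return ClinicalTargets(sbp=sbp, dbp=dbp, stroke_volume=sv, ejection_fraction=ef)


@dataclass
class SyntheticPatientConfig:
    seed: int = 0
    # outer semi-axes [cm] of the half-ellipsoid epicardial surface
    semi_axes: Tuple[float, float, float] = (3.8, 3.8, 5.2)
    wall_thickness: float = 1.2
    # mesh resolution: circumferential, apex-to-base, transmural divisions
    n_circ: int = 24
    n_long: int = 12
    n_radial: int = 3
    apex_cut: float = 0.25  # colatitude [rad] of the apex opening
    n_lv_outlets: int = 16
    flow_sigma: float = 0.4  # lognormal dispersion of ground-truth flows
    mbf_noise_cv: float = 0.1
    patient: int = 1
    targets: Optional[ClinicalTargets] = None

    def __post_init__(self):
        if self.n_lv_outlets < 2:
            raise ValueError("n_lv_outlets must be >= 2")
        if self.flow_sigma < 0 or self.mbf_noise_cv < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if self.wall_thickness <= 0:
            raise ValueError("wall thickness must be > 0")
        if min(self.semi_axes) <= self.wall_thickness:
            raise ValueError("wall thickness exceeds a semi-axis")
        if self.targets is None:
            self.targets = table_targets(self.patient)


# ---------------------------------------------------------------------------
# LV mesh
# ---------------------------------------------------------------------------

def _shell_point(cfg: SyntheticPatientConfig, u: float, th: float, w: float) -> np.ndarray:
    """Point at longitude u, colatitude th (from apex), transmural w in [0,1]
    (0 = endocardial, 1 = epicardial)."""
    ao, bo, co = cfg.semi_axes
    t = cfg.wall_thickness
    ai, bi, ci = ao - t, bo - t, co - t
    a = ai + w * (ao - ai)
    b = bi + w * (bo - bi)
    c = ci + w * (co - ci)
    return np.array(
        [a * np.sin(th) * np.cos(u), b * np.sin(th) * np.sin(u), -c * np.cos(th)]
    )


# 6-tet decomposition of a hexahedron (corner order: standard VTK hexa)
_HEX_TETS = [
    (0, 1, 3, 7), (0, 1, 7, 5), (0, 5, 7, 4),
    (1, 2, 3, 7), (1, 2, 7, 6), (1, 6, 7, 5),
]


def make_lv_mesh(config: SyntheticPatientConfig) -> LVMesh:
    """Structured tetrahedral mesh of the truncated half-ellipsoid shell.

    The grid is periodic circumferentially and graded linearly between the
    endocardial and epicardial surfaces; each hexahedral cell is split into
    six positively oriented tetrahedra.
    """
    nu, nv, nw = config.n_circ, config.n_long, config.n_radial
    if nu < 4 or nv < 2 or nw < 1:
        raise ValueError("resolution too coarse")
    us = np.linspace(0.0, 2 * np.pi, nu, endpoint=False)
    ths = np.linspace(config.apex_cut, np.pi / 2, nv + 1)
    ws = np.linspace(0.0, 1.0, nw + 1)

    def nid(iu: int, iv: int, iw: int) -> int:
        return (iv * (nw + 1) + iw) * nu + (iu % nu)

    nodes = np.empty(((nv + 1) * (nw + 1) * nu, 3))
    for iv, th in enumerate(ths):
        for iw, w in enumerate(ws):
            for iu, u in enumerate(us):
                nodes[nid(iu, iv, iw)] = _shell_point(config, u, th, w)

    tets: List[Tuple[int, int, int, int]] = []
    for iv in range(nv):
        for iw in range(nw):
            for iu in range(nu):
                corners = [
                    nid(iu, iv, iw), nid(iu + 1, iv, iw),
                    nid(iu + 1, iv + 1, iw), nid(iu, iv + 1, iw),
                    nid(iu, iv, iw + 1), nid(iu + 1, iv, iw + 1),
                    nid(iu + 1, iv + 1, iw + 1), nid(iu, iv + 1, iw + 1),
                ]
                for t in _HEX_TETS:
                    tets.append(tuple(corners[k] for k in t))

    tets = np.array(tets, dtype=np.int64)
    # fix orientation where the parametric map is left-handed
    p = nodes[tets]
    vol6 = np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0], np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
    )
    flip = vol6 < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return LVMesh(nodes=nodes, tets=tets)


def analytic_shell_volume(config: SyntheticPatientConfig) -> float:
    """Exact volume [mL] of the continuum truncated half-ellipsoid shell."""
    ao, bo, co = config.semi_axes
    t = config.wall_thickness
    x = np.cos(config.apex_cut)

    def half(a, b, c):
        # ellipsoid sector between colatitude apex_cut and pi/2 (from apex)
        return np.pi * a * b * c * (x - x**3 / 3.0)

    return half(ao, bo, co) - half(ao - t, bo - t, co - t)


# ---------------------------------------------------------------------------
# Epicardial tree
# ---------------------------------------------------------------------------

def _surface_targets(config: SyntheticPatientConfig, n: int, u0: float, u1: float,
                     rng: np.random.Generator) -> np.ndarray:
    """n points on the epicardial surface inside longitude arc [u0, u1]."""
    golden = (np.sqrt(5.0) - 1.0) / 2.0
    pts = []
    for k in range(n):
        frac = (k + 0.5) / n
        u = u0 + ((k * golden + 0.11) % 1.0) * (u1 - u0)
        th = config.apex_cut + 0.15 + frac * (np.pi / 2 - config.apex_cut - 0.3)
        pts.append(_shell_point(config, u, th, 1.0))
    return np.array(pts)


class _TreeBuilder:
    def __init__(self):
        self.segments: List[VesselSegment] = []

    def add(self, parent_id, p0, p1, radius, origin="synthetic", perfuses_lv=True) -> int:
        sid = len(self.segments)
        self.segments.append(
            VesselSegment(sid, parent_id, np.asarray(p0, float), np.asarray(p1, float),
                          radius, origin, perfuses_lv)
        )
        return sid

    def build_bifurcating(self, parent_id: int, entry: np.ndarray,
                          points: np.ndarray, radius: float, gamma: float = 3.0,
                          perfuses_lv: bool = True) -> List[int]:
        """Recursive-bisection binary tree over ``points``; returns leaf ids."""
        if len(points) == 1:
            self.add(parent_id, entry, points[0], radius, perfuses_lv=perfuses_lv)
            return [len(self.segments) - 1]
        centroid = points.mean(axis=0)
        junction = entry + 0.55 * (centroid - entry)
        if np.linalg.norm(junction - entry) < 1e-9:
            junction = entry + np.array([0.0, 0.0, -0.05])
        trunk = self.add(parent_id, entry, junction, radius, perfuses_lv=perfuses_lv)
        spread = points - centroid
        axis = np.argmax(spread.max(axis=0) - spread.min(axis=0))
        order = np.argsort(points[:, axis], kind="stable")
        half = len(points) // 2
        leaves = []
        for grp in (points[order[:half]], points[order[half:]]):
            # Murray gamma-law split by terminal count
            frac = len(grp) / len(points)
            r = radius * frac ** (1.0 / gamma)
            leaves += self.build_bifurcating(trunk, junction, grp, r,
                                            gamma, perfuses_lv)
        return leaves


def make_epicardial_tree(config: SyntheticPatientConfig, mesh: LVMesh) -> VesselTree:
    """Aortic root + left/right coronary mains + bifurcating epicardial
    branches whose LV-perfusing outlets lie exactly on the epicardial
    surface.  Two proximal right-coronary leaves are flagged
    ``perfuses_lv=False``; one large non-LV leaf is the systemic (aortic)
    outlet (see :func:`aortic_outlet_id`)."""
    rng = np.random.default_rng(config.seed)
    ao, bo, co = config.semi_axes
    n_left = max(1, int(round(config.n_lv_outlets * 0.75)))
    n_right = config.n_lv_outlets - n_left
    if n_right == 0:
        n_left -= 1
        n_right = 1

    b = _TreeBuilder()
    root_top = np.array([0.0, 0.0, 2.5])
    ostium = np.array([0.0, 0.0, 1.5])
    root = b.add(None, root_top, ostium, 1.0, origin="image_based", perfuses_lv=False)
    # systemic continuation of the aorta (Windkessel attaches here)
    b.add(root, ostium, ostium + np.array([0.8, 0.0, 1.2]), 0.95,
          origin="image_based", perfuses_lv=False)

    left_targets = _surface_targets(config, n_left, 0.15 * np.pi, 1.15 * np.pi, rng)
    right_targets = _surface_targets(config, n_right, 1.25 * np.pi, 1.9 * np.pi, rng)

    # left main from the ostium to above the epicardium on the left side
    lm_end = np.array([0.55 * ao, 0.35 * bo, 0.6])
    lm = b.add(root, ostium, lm_end, 0.20, origin="image_based", perfuses_lv=False)
    b.build_bifurcating(lm, lm_end, left_targets, 0.19)

    # right main; carries two proximal non-LV leaves plus distal LV branches
    rm_end = np.array([-0.5 * ao, -0.4 * bo, 0.5])
    rm = b.add(root, ostium, rm_end, 0.17, origin="image_based", perfuses_lv=False)
    rv1 = rm_end + np.array([-0.8, -0.6, -0.8])
    rv2 = rm_end + np.array([-0.4, -1.0, -1.2])
    b.add(rm, rm_end, rv1, 0.10, origin="image_based", perfuses_lv=False)
    junction = rm_end + np.array([-0.2, -0.3, -0.9])
    rstem = b.add(rm, rm_end, junction, 0.15, origin="image_based", perfuses_lv=False)
    b.add(rstem, junction, rv2, 0.08, origin="image_based", perfuses_lv=False)
    b.build_bifurcating(rstem, junction, right_targets, 0.13)

    return VesselTree(b.segments, root)


def aortic_outlet_id(tree: VesselTree) -> int:
    """The systemic (aortic) outlet: the largest-radius non-LV leaf."""
    cands = [sid for sid in tree.outlet_ids if not tree.segments[sid].perfuses_lv]
    if not cands:
        raise ValueError("tree has no non-LV outlet")
    return max(cands, key=lambda sid: tree.segments[sid].radius)


def non_lv_coronary_outlets(tree: VesselTree) -> List[int]:
    """Coronary leaves not perfusing the LV (excludes the aortic outlet)."""
    ao = aortic_outlet_id(tree)
    return [sid for sid in tree.outlet_ids
            if not tree.segments[sid].perfuses_lv and sid != ao]


# ---------------------------------------------------------------------------
# Ground-truth flows and MBF
# ---------------------------------------------------------------------------

def morphometric_q_lv(v_lv: float) -> float:
    """Total LV-perfusing flow from the morphometric rule, in mL/min."""
    return 3.41 * v_lv**0.75


def make_ground_truth_flows(config: SyntheticPatientConfig, tree: VesselTree,
                            v_lv: Optional[float] = None) -> Dict[int, float]:
    """Per-LV-outlet ground-truth flows [mL/s].

    Diameter-law (exponent 2.6) flow shares perturbed by seeded lognormal
    multipliers with dispersion ``flow_sigma``, renormalized to the
    morphometric Q_LV.  With ``flow_sigma == 0`` the truth is exactly the
    diameter-law split.
    """
    lv = tree.lv_outlet_ids
    if not lv:
        raise ValueError("tree has no LV-perfusing outlets")
    if v_lv is None:
        v_lv = analytic_shell_volume(config)
    q_lv = morphometric_q_lv(v_lv) / 60.0  # mL/s
    d = np.array([2.0 * tree.segments[sid].radius for sid in lv])
    shares = d**2.6
    rng = np.random.default_rng(config.seed + 1)
    mult = np.exp(rng.normal(0.0, config.flow_sigma, size=len(lv)))
    shares = shares * mult
    shares /= shares.sum()
    return {sid: q_lv * s for sid, s in zip(lv, shares)}


def murray_fractions(tree: VesselTree, exponent: float = 2.6) -> Dict[int, float]:
    """Diameter-law flow fractions over the LV outlets."""
    lv = tree.lv_outlet_ids
    d = np.array([2.0 * tree.segments[sid].radius for sid in lv])
    f = d**exponent
    f /= f.sum()
    return dict(zip(lv, f))


def make_mbf_field(config: SyntheticPatientConfig, mesh: LVMesh,
                   tmap: terr.PerfusionTerritoryMap,
                   true_flows: Dict[int, float]) -> np.ndarray:
    """Nodal MBF [mL/min/100 mL] whose per-territory integral equals the
    ground-truth flow exactly.

    Piecewise-uniform per territory, multiplied by seeded lognormal noise
    with coefficient of variation ``mbf_noise_cv``, then renormalized per
    territory so the control-volume integrals are preserved.
    """
    rng = np.random.default_rng(config.seed + 2)
    cv = mesh.node_control_volumes()
    mbf = np.empty(len(mesh.nodes))
    for k, sid in enumerate(tmap.outlet_ids):
        mask = tmap.nodal_label == k
        vol = cv[mask].sum()
        q = true_flows[sid]  # mL/s
        base = flow_density_to_mbf_clinical(q / vol)
        vals = np.full(mask.sum(), base)
        if config.mbf_noise_cv > 0:
            sigma = np.sqrt(np.log(1.0 + config.mbf_noise_cv**2))
            vals = vals * np.exp(rng.normal(0.0, sigma, size=len(vals)))
            # renormalize so the territory integral is exact
            integral = (vals / 6000.0 * cv[mask]).sum()
            vals *= q / integral
        mbf[mask] = vals
    return mbf


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPatient:
    config: SyntheticPatientConfig
    mesh: LVMesh
    tree: VesselTree
    territory_map: terr.PerfusionTerritoryMap
    true_flows: Dict[int, float]
    targets: ClinicalTargets

    @property
    def v_lv(self) -> float:
        return self.mesh.total_volume

    @property
    def q_lv(self) -> float:
        """Total LV flow [mL/s] implied by the MBF field."""
        return float(sum(self.true_flows.values()))


def make_patient(config: Optional[SyntheticPatientConfig] = None) -> SyntheticPatient:
    """Generate the full synthetic patient bundle deterministically."""
    cfg = config or SyntheticPatientConfig()
    mesh = make_lv_mesh(cfg)
    tree = make_epicardial_tree(cfg, mesh)
    tmap = terr.assign_territories(mesh, terr.outlet_points(tree))
    flows = make_ground_truth_flows(cfg, tree, v_lv=mesh.total_volume)
    mesh.nodal_mbf = make_mbf_field(cfg, mesh, tmap, flows)
    terr.integrate_mbf(mesh, tmap)
    return SyntheticPatient(cfg, mesh, tree, tmap, flows, cfg.targets)
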