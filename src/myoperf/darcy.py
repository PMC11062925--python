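"""Single-compartment Darcy perfusion on the LV tet mesh.

Steady pressure problem (linear tet FEM, natural/zero-flux boundaries)::

    -div(k grad p) + (beta_src + beta_snk) p = beta_src p_src + beta_snk p_snk

with the conductances parameterized from the target capillary pressure::

    beta_src = Q_LV / (V_LV (pbar_src - p_cap))
    beta_snk = Q_LV / (V_LV (p_cap - p_snk))

so a spatially uniform source p_src = pbar_src yields p = p_cap exactly and
total MBF = integral beta_src (p_src - p) dv = Q_LV.  Mass terms are
assembled consistently (not lumped) to preserve that closed form.

Internally pressures are dyn/cm^2, k is converted from the configured
cm^2/Pa/s, and MBF densities are reported clinically as mL/min/100 mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core_model import LVMesh
from .core_model.units import PA, flow_density_to_mbf_clinical, mmhg_to_barye
from .territories import PerfusionTerritoryMap

#: fixed myocardial permeability [cm^2 Pa^-1 s^-1]
DEFAULT_PERMEABILITY = 2e-5

#: target capillary pressure [mmHg]
P_CAP_MMHG = 15.0

#: venous sink pressure [mmHg]
P_SNK_MMHG = 0.0


def make_betas(q_lv: float, v_lv: float, pbar_src: float, p_cap: float,
               p_snk: float) -> Tuple[float, float]:
    """Source/sink conductances [1/(dyn/cm^2)/s] from CGS pressures.

    q_lv [mL/s], v_lv [mL], pressures [dyn/cm^2]; requires
    pbar_src > p_cap > p_snk.
    """
    if not (pbar_src > p_cap > p_snk):
        raise ValueError("require pbar_src > p_cap > p_snk")
    beta_src = q_lv / (v_lv * (pbar_src - p_cap))
    beta_snk = q_lv / (v_lv * (p_cap - p_snk))
    return beta_src, beta_snk


def build_source_field(tmap: PerfusionTerritoryMap,
                       p_src: Dict[int, float]) -> np.ndarray:
    """Piecewise-constant nodal pressure-source field by territory label."""
    missing = set(tmap.outlet_ids) - set(p_src)
    if missing:
        raise ValueError(f"missing source pressure for outlets {sorted(missing)}")
    vals = np.array([p_src[sid] for sid in tmap.outlet_ids])
    return vals[tmap.nodal_label]


@dataclass
class DarcyProblem:
    mesh: LVMesh
    nodal_p_src: np.ndarray  # [dyn/cm^2]
    q_lv: float  # [mL/s]
    p_cap: float = mmhg_to_barye(P_CAP_MMHG)
    p_snk: float = mmhg_to_barye(P_SNK_MMHG)
    permeability: float = DEFAULT_PERMEABILITY  # cm^2/Pa/s
    pbar_src: Optional[float] = None  # volume-weighted mean source

    def __post_init__(self):
        self.nodal_p_src = np.asarray(self.nodal_p_src, dtype=float)
        if self.nodal_p_src.shape != (len(self.mesh.nodes),):
            raise ValueError("nodal_p_src length must match node count")
        if self.permeability <= 0:
            raise ValueError("permeability must be > 0")
        if self.pbar_src is None:
            cv = self.mesh.node_control_volumes()
            self.pbar_src = float((self.nodal_p_src * cv).sum() / cv.sum())

    @property
    def v_lv(self) -> float:
        return self.mesh.total_volume

    @property
    def betas(self) -> Tuple[float, float]:
        return make_betas(self.q_lv, self.v_lv, self.pbar_src, self.p_cap, self.p_snk)

    @property
    def k_cgs(self) -> float:
        """Permeability converted so that k grad p has units cm/s with p in
        dyn/cm^2 (cm^2 Pa^-1 s^-1 -> cm^2 barye^-1 s^-1)."""
        return self.permeability / PA


@dataclass
class DarcySolution:
    problem: DarcyProblem
    nodal_p: np.ndarray  # [dyn/cm^2]
    residual: float

    def nodal_mbf_density(self) -> np.ndarray:
        """Nodal beta_src (p_src - p), clinically scaled [mL/min/100 mL]."""
        beta_src, _ = self.problem.betas
        return flow_density_to_mbf_clinical(
            beta_src * (self.problem.nodal_p_src - self.nodal_p)
        )

    def source_integral(self) -> float:
        """Total inflow integral beta_src (p_src - p) dv [mL/s]."""
        beta_src, _ = self.problem.betas
        M = _mass_matrix(self.problem.mesh)
        return float(beta_src * np.ones(len(self.nodal_p))
                     @ (M @ (self.problem.nodal_p_src - self.nodal_p)))

    def sink_integral(self) -> float:
        """Total outflow integral beta_snk (p - p_snk) dv [mL/s]."""
        _, beta_snk = self.problem.betas
        M = _mass_matrix(self.problem.mesh)
        return float(beta_snk * np.ones(len(self.nodal_p))
                     @ (M @ (self.nodal_p - self.problem.p_snk)))


_mass_cache: dict = {}


def _tet_gradients(mesh: LVMesh):
    """Per-tet shape-function gradients (M, 4, 3) and volumes (M,)."""
    p = mesh.nodes[mesh.tets]
    v = mesh.tet_volumes()
    grads = np.empty((len(mesh.tets), 4, 3))
    # gradient of barycentric coordinate i: opposite-face normal / (3 V) style
    for i in range(4):
        others = [j for j in range(4) if j != i]
        a, b, c = p[:, others[0]], p[:, others[1]], p[:, others[2]]
        n = np.cross(b - a, c - a)  # normal of the opposite face
        # orient toward vertex i
        sgn = np.sign(np.einsum("ij,ij->i", p[:, i] - a, n))
        n = n * sgn[:, None]
        grads[:, i, :] = n / (6.0 * v)[:, None]
    return grads, v


def _stiffness_matrix(mesh: LVMesh) -> sp.csr_matrix:
    grads, v = _tet_gradients(mesh)
    n = len(mesh.nodes)
    rows, cols, vals = [], [], []
    for i in range(4):
        for j in range(4):
            rows.append(mesh.tets[:, i])
            cols.append(mesh.tets[:, j])
            vals.append(np.einsum("kd,kd->k", grads[:, i], grads[:, j]) * v)
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def _mass_matrix(mesh: LVMesh) -> sp.csr_matrix:
    key = id(mesh)
    cached = _mass_cache.get(key)
    if cached is not None and cached[0] is mesh:
        return cached[1]
    v = mesh.tet_volumes()
    n = len(mesh.nodes)
    rows, cols, vals = [], [], []
    for i in range(4):
        for j in range(4):
            w = v / 10.0 if i == j else v / 20.0  # consistent linear-tet mass
            rows.append(mesh.tets[:, i])
            cols.append(mesh.tets[:, j])
            vals.append(w)
    M = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    _mass_cache[key] = (mesh, M)
    return M


def solve_darcy(problem: DarcyProblem, forcing: Optional[np.ndarray] = None,
                rtol: float = 1e-12) -> DarcySolution:
    """Solve the steady reaction-diffusion system for the Darcy pressure.

    ``forcing`` (optional, [1/s] nodal values) adds a volumetric source
    term for manufactured-solution verification.  The SPD system is solved
    directly; the relative residual is reported on the solution.
    """
    mesh = problem.mesh
    beta_src, beta_snk = problem.betas
    K = _stiffness_matrix(mesh) * problem.k_cgs
    M = _mass_matrix(mesh)
    A = K + (beta_src + beta_snk) * M
    rhs = M @ (beta_src * problem.nodal_p_src
               + beta_snk * problem.p_snk * np.ones(len(mesh.nodes)))
    if forcing is not None:
        rhs = rhs + M @ np.asarray(forcing, dtype=float)
    p = spla.spsolve(A.tocsc(), rhs)
    res = float(np.linalg.norm(A @ p - rhs) / max(np.linalg.norm(rhs), 1e-300))
    if not np.all(np.isfinite(p)):
        raise RuntimeError("Darcy solve failed (singular assembly?)")
    return DarcySolution(problem=problem, nodal_p=p, residual=res)


def compute_mbf(solution: DarcySolution, tmap: PerfusionTerritoryMap
                ) -> Tuple[np.ndarray, float]:
    """Per-territory MBF_{V_i} = int_{V_i} beta_src (p_src - p) dv [mL/s].

    Returns (per-territory flows ordered like ``tmap.outlet_ids``, total).
    The territory integral restricts the consistent-mass integrand to the
    territory's nodes (partition of unity over nodes).
    """
    beta_src, _ = solution.problem.betas
    M = _mass_matrix(solution.problem.mesh)
    nodal_integral = beta_src * (M @ (solution.problem.nodal_p_src - solution.nodal_p))
    flows = np.bincount(tmap.nodal_label, weights=nodal_integral,
                        minlength=len(tmap.outlet_ids))
    return flows, float(nodal_integral.sum())


def required_sources(tmap: PerfusionTerritoryMap, q_lv: float, v_lv: float,
                     pbar_src: float,
                     p_cap: float = mmhg_to_barye(P_CAP_MMHG),
                     p_snk: float = mmhg_to_barye(P_SNK_MMHG)) -> Dict[int, float]:
    """Invert the MBF integral for the territory source pressures:

    p_src^i = MBF_{V_i} / (beta_src V_i) + p_cap

    Self-consistent: the volume-weighted mean of the returned sources
    equals ``pbar_src`` whenever the territory flows sum to q_lv.
    """
    beta_src, _ = make_betas(q_lv, v_lv, pbar_src, p_cap, p_snk)
    out: Dict[int, float] = {}
    for k, sid in enumerate(tmap.outlet_ids):
        out[sid] = tmap.flows[k] / (beta_src * tmap.volumes[k]) + p_cap
    return out
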