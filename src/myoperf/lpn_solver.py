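"""Time integration and steady solution of 0D circulation networks.

``simulate`` integrates the closed-loop DAE with backward Euler and a
damped Newton solve per step until cycle-to-cycle periodicity; metrics are
computed on the final cycle.  ``steady_solve`` solves the resistive
skeleton (capacitors open, inductors short) as one sparse linear system —
the fast inner loop used by the flow-tuning stages.  FFR along a branch is
the cycle-averaged (or steady) pressure at each node divided by the
aortic pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network0d import (
    Capacitor,
    FlowSource,
    HeartChamber,
    Network0D,
    Resistor,
    Valve,
    VesselBranch,
)

FFR_ISCHEMIA_THRESHOLD = 0.80


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------


class _Compiled:
    """Index maps and element arrays for fast residual/Jacobian assembly."""

    def __init__(self, net: Network0D):
        self.net = net
        names = net.node_names()
        self.node_index = {n: i for i, n in enumerate(names)}
        self.names = names
        self.n_nodes = len(names)
        self.fixed_idx = np.array([self.node_index[n] for n in net.fixed], dtype=int)
        self.fixed_vals = list(net.fixed.values())
        free = [i for i, n in enumerate(names) if n not in net.fixed]
        self.free_idx = np.array(free, dtype=int)
        self.row_of_node = -np.ones(self.n_nodes, dtype=int)  # KCL row per node
        self.row_of_node[self.free_idx] = np.arange(len(free))
        self.nf = len(free)

        self.resistors = [e for e in net.elements if isinstance(e, Resistor)]
        self.valves = [e for e in net.elements if isinstance(e, Valve)]
        self.caps = [e for e in net.elements if isinstance(e, Capacitor)]
        self.branches = [e for e in net.elements if isinstance(e, VesselBranch)]
        self.sources = [e for e in net.elements if isinstance(e, FlowSource)]
        self.chambers = net.chambers

        idx = self.node_index
        self.res_n = np.array([[idx[e.n1], idx[e.n2]] for e in self.resistors],
                              dtype=int).reshape(-1, 2)
        self.valve_n = np.array([[idx[e.n1], idx[e.n2]] for e in self.valves],
                                dtype=int).reshape(-1, 2)
        self.cap_n = np.array([idx[e.node] for e in self.caps], dtype=int)
        self.cap_ref = np.array(
            [idx[e.ref_node] if e.ref_node is not None else -1 for e in self.caps],
            dtype=int)
        self.cap_scale = np.array([e.ref_scale for e in self.caps])
        self.br_n = np.array([[idx[e.n1], idx[e.n2]] for e in self.branches],
                             dtype=int).reshape(-1, 2)
        self.src_n = np.array([[idx[e.n1], idx[e.n2]] for e in self.sources],
                              dtype=int).reshape(-1, 2)
        self.ch_n = np.array([idx[c.node] for c in self.chambers], dtype=int)

        self.nb = len(self.branches)
        self.nc = len(self.chambers)
        self.nx = self.nf + self.nb + self.nc

    # -- state <-> physical -------------------------------------------------

    def refresh_values(self) -> None:
        """Pull current (possibly mutated) element values into arrays."""
        self.res_R = np.array([e.R for e in self.resistors])
        self.valve_Ro = np.array([e.R_open for e in self.valves])
        self.valve_Rl = np.array([e.R_leak for e in self.valves])
        self.valve_w = np.array([e.w for e in self.valves])
        self.cap_C = np.array([e.C for e in self.caps])
        self.br_R = np.array([e.R for e in self.branches])
        self.br_L = np.array([e.L for e in self.branches])
        self.ch_V0 = np.array([c.V0 for c in self.chambers])

    def fixed_pressures(self, t: float) -> np.ndarray:
        return np.array([v(t) if callable(v) else v for v in self.fixed_vals])

    def pressures(self, x: np.ndarray, t: float) -> np.ndarray:
        P = np.zeros(self.n_nodes)
        P[self.free_idx] = x[: self.nf]
        if len(self.fixed_idx):
            P[self.fixed_idx] = self.fixed_pressures(t)
        return P

    def source_flows(self, t: float) -> np.ndarray:
        return np.array([e.q(t) if callable(e.q) else e.q for e in self.sources])

    def elastances(self, t: float) -> np.ndarray:
        T = self.net.period
        return np.array([c.elastance(t, T) for c in self.chambers])


def _valve_flow(dp: np.ndarray, Ro: np.ndarray, Rl: np.ndarray, w: np.ndarray):
    """Smooth-diode flow and its derivative w.r.t. dp."""
    z = np.clip(dp / w, -50.0, 50.0)
    sig = 1.0 / (1.0 + np.exp(-z))
    g = sig / Ro + (1.0 - sig) / Rl
    q = dp * g
    dgdp = sig * (1.0 - sig) / w * (1.0 / Ro - 1.0 / Rl)
    return q, g + dp * dgdp


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class CardiacMetrics:
    sbp: float  # mmHg
    dbp: float  # mmHg
    stroke_volume: float  # mL
    ejection_fraction: float
    edv: float
    esv: float
    cardiac_output: float  # L/min

    def to_dict(self):
        return dict(self.__dict__)


@dataclass
class SimulationResult:
    """Waveforms over the final (converged) cycle plus convergence info."""

    compiled: _Compiled
    time: np.ndarray
    P: np.ndarray  # (nt, n_nodes)
    Q_branch: np.ndarray  # (nt, nb)
    V_chamber: np.ndarray  # (nt, nc)
    cycles_run: int
    converged: bool
    periodicity: float
    final_state: Optional[np.ndarray] = None

    def node_pressure(self, name: str) -> np.ndarray:
        return self.P[:, self.compiled.node_index[name]]

    def mean_pressure(self, name: str) -> float:
        return float(np.trapezoid(self.node_pressure(name), self.time)
                     / (self.time[-1] - self.time[0]))

    def resistor_flow(self, elem: Resistor) -> np.ndarray:
        i1 = self.compiled.node_index[elem.n1]
        i2 = self.compiled.node_index[elem.n2]
        return (self.P[:, i1] - self.P[:, i2]) / elem.R

    def mean_resistor_flow(self, elem: Resistor) -> float:
        q = self.resistor_flow(elem)
        return float(np.trapezoid(q, self.time) / (self.time[-1] - self.time[0]))

    def branch_flow(self, elem: VesselBranch) -> np.ndarray:
        k = self.compiled.branches.index(elem)
        return self.Q_branch[:, k]

    def chamber_volume(self, node: str) -> np.ndarray:
        for k, c in enumerate(self.compiled.chambers):
            if c.node == node:
                return self.V_chamber[:, k]
        raise KeyError(f"no chamber at node {node}")

    def outlet_averages(self, aortic_node: str = "aorta") -> Dict[int, dict]:
        """Cycle-averaged P^i, Q^i and microvascular P_mu^i per outlet."""
        out = {}
        for oid, h in self.compiled.net.outlet_blocks.items():
            P_i = self.mean_pressure(h.outlet_node)
            Q_i = self.mean_resistor_flow(h.r_a)
            out[oid] = {
                "P": P_i,
                "Q": Q_i,
                "P_mu": P_i - Q_i * h.r_a.R,
            }
        return out


def cardiac_metrics(result: SimulationResult, aortic_node: str = "aorta",
                    lv_node: str = "LV") -> CardiacMetrics:
    """sbp/dbp from the aortic waveform; SV/EF/CO from the LV volume trace."""
    from .core_model.units import barye_to_mmhg

    pa = result.node_pressure(aortic_node)
    v = result.chamber_volume(lv_node)
    edv, esv = float(v.max()), float(v.min())
    sv = edv - esv
    T = result.time[-1] - result.time[0]
    return CardiacMetrics(
        sbp=barye_to_mmhg(float(pa.max())),
        dbp=barye_to_mmhg(float(pa.min())),
        stroke_volume=sv,
        ejection_fraction=sv / edv if edv > 0 else 0.0,
        edv=edv,
        esv=esv,
        cardiac_output=sv / T * 60.0 / 1000.0,
    )


# ---------------------------------------------------------------------------
# transient solver
# ---------------------------------------------------------------------------


def _assemble(c: _Compiled, x: np.ndarray, xp: np.ndarray, t: float, tp: float,
              dt: float, Pfix: np.ndarray, Pfix_p: np.ndarray):
    """Backward-Euler residual and dense Jacobian at time t."""
    nf, nb, nc = c.nf, c.nb, c.nc
    P = np.zeros(c.n_nodes)
    P[c.free_idx] = x[:nf]
    if len(c.fixed_idx):
        P[c.fixed_idx] = Pfix
    Pp = np.zeros(c.n_nodes)
    Pp[c.free_idx] = xp[:nf]
    if len(c.fixed_idx):
        Pp[c.fixed_idx] = Pfix_p
    Q = x[nf: nf + nb]
    Qp = xp[nf: nf + nb]
    V = x[nf + nb:]
    Vp = xp[nf + nb:]

    res = np.zeros(c.nx)
    J = np.zeros((c.nx, c.nx))
    row = c.row_of_node  # node -> KCL row (-1 if fixed)
    col_of_node = row  # columns for free node pressures coincide with rows

    # resistors
    if len(c.resistors):
        n1, n2 = c.res_n[:, 0], c.res_n[:, 1]
        q = (P[n1] - P[n2]) / c.res_R
        g = 1.0 / c.res_R
        _scatter_two_node(res, J, row, n1, n2, q, g)

    # valves
    if len(c.valves):
        n1, n2 = c.valve_n[:, 0], c.valve_n[:, 1]
        dp = P[n1] - P[n2]
        q, g = _valve_flow(dp, c.valve_Ro, c.valve_Rl, c.valve_w)
        _scatter_two_node(res, J, row, n1, n2, q, g)

    # capacitors (charging current leaves the node)
    if len(c.caps):
        n = c.cap_n
        ref = c.cap_ref
        s = c.cap_scale
        pref = np.where(ref >= 0, P[np.maximum(ref, 0)] * s, 0.0)
        pref_p = np.where(ref >= 0, Pp[np.maximum(ref, 0)] * s, 0.0)
        qc = c.cap_C * ((P[n] - pref) - (Pp[n] - pref_p)) / dt
        rn = row[n]
        for k in range(len(n)):
            if rn[k] >= 0:
                res[rn[k]] -= qc[k]
                J[rn[k], col_of_node[n[k]]] -= c.cap_C[k] / dt
                if ref[k] >= 0 and row[ref[k]] >= 0:
                    J[rn[k], col_of_node[ref[k]]] += c.cap_C[k] * s[k] / dt

    # vessel branches (flow states)
    for k in range(nb):
        n1, n2 = c.br_n[k]
        qk = Q[k]
        r1, r2 = row[n1], row[n2]
        if r1 >= 0:
            res[r1] -= qk
            J[r1, nf + k] -= 1.0
        if r2 >= 0:
            res[r2] += qk
            J[r2, nf + k] += 1.0
        rr = nf + k
        res[rr] = c.br_L[k] * (qk - Qp[k]) / dt + c.br_R[k] * qk - (P[n1] - P[n2])
        J[rr, rr] = c.br_L[k] / dt + c.br_R[k]
        if r1 >= 0:
            J[rr, col_of_node[n1]] -= 1.0
        if r2 >= 0:
            J[rr, col_of_node[n2]] += 1.0

    # flow sources
    if len(c.sources):
        qs = c.source_flows(t)
        for k in range(len(c.sources)):
            n1, n2 = c.src_n[k]
            if row[n1] >= 0:
                res[row[n1]] -= qs[k]
            if row[n2] >= 0:
                res[row[n2]] += qs[k]

    # chambers
    if nc:
        E = c.elastances(t)
        for k in range(nc):
            n = c.ch_n[k]
            rn = row[n]
            # volume accumulation at the chamber node
            res[rn] -= (V[k] - Vp[k]) / dt
            J[rn, nf + nb + k] -= 1.0 / dt
            # elastance relation
            rr = nf + nb + k
            res[rr] = P[n] - E[k] * (V[k] - c.ch_V0[k])
            J[rr, col_of_node[n]] += 1.0
            J[rr, nf + nb + k] -= E[k]

    return res, J


def _scatter_two_node(res, J, row, n1, n2, q, g):
    """Add a two-node algebraic flow q with conductance g to KCL rows."""
    r1 = row[n1]  # KCL rows; also the pressure-column index of a free node
    r2 = row[n2]
    m1 = r1 >= 0
    m2 = r2 >= 0
    both = m1 & m2
    np.add.at(res, r1[m1], -q[m1])
    np.add.at(res, r2[m2], q[m2])
    np.add.at(J, (r1[m1], r1[m1]), -g[m1])
    np.add.at(J, (r1[both], r2[both]), g[both])
    np.add.at(J, (r2[m2], r2[m2]), -g[m2])
    np.add.at(J, (r2[both], r1[both]), g[both])


def initial_state(c: _Compiled, pressures: Optional[Dict[str, float]] = None,
                  default_pressure: float = 0.0) -> np.ndarray:
    """Assemble a starting state from named pressure guesses and chamber
    initial volumes."""
    x = np.zeros(c.nx)
    p = np.full(c.nf, default_pressure)
    if pressures:
        for name, val in pressures.items():
            i = c.node_index.get(name)
            if i is not None and c.row_of_node[i] >= 0:
                p[c.row_of_node[i]] = val
    x[: c.nf] = p
    for k, ch in enumerate(c.chambers):
        x[c.nf + c.nb + k] = ch.V_init
    return x


def simulate(net: Network0D, n_cycles_max: int = 20, dt: Optional[float] = None,
             periodicity_tol: float = 1e-3, n_store: Optional[int] = None,
             init_pressures: Optional[Dict[str, float]] = None,
             newton_tol: float = 1e-8, newton_maxiter: int = 25,
             x0: Optional[np.ndarray] = None) -> SimulationResult:
    """Integrate to periodic convergence with backward Euler.

    dt defaults to T/2000.  Cycle-to-cycle convergence is measured as the
    relative L2 change of the full state sampled at cycle end.  On Newton
    divergence the step is retried with a halved dt (up to 4 sub-splits)
    before failing with diagnostics.
    """
    c = _Compiled(net)
    c.refresh_values()
    T = net.period
    if dt is None:
        dt = T / 2000.0
    nt = int(round(T / dt))
    dt = T / nt

    x = initial_state(c, init_pressures, default_pressure=0.0)
    if x0 is not None and len(x0) == c.nx:
        x = np.asarray(x0, dtype=float).copy()
    elif init_pressures is None and "aorta" in c.node_index:
        # physiologic defaults for closed-loop nets
        guesses = {}
        for name in c.names:
            if name in ("sysven", "RA", "pulm", "LA", "PA", "RV"):
                guesses[name] = 12.0 * 1333.22
            else:
                guesses[name] = 85.0 * 1333.22
        x = initial_state(c, guesses)

    # ramp Newton in: solve the first instant with relaxation
    P_hist = np.empty((nt + 1, c.n_nodes))
    Q_hist = np.empty((nt + 1, c.nb))
    V_hist = np.empty((nt + 1, c.nc))
    times = np.linspace(0.0, T, nt + 1)

    prev_end = None
    periodicity = np.inf
    cycles = 0
    scale = None
    for cycle in range(n_cycles_max):
        t0 = cycle * T
        P_hist[0] = c.pressures(x, t0)
        Q_hist[0] = x[c.nf: c.nf + c.nb]
        V_hist[0] = x[c.nf + c.nb:]
        for k in range(nt):
            t_new = t0 + (k + 1) * dt
            x = _step(c, x, t_new, dt, newton_tol, newton_maxiter)
            P_hist[k + 1] = c.pressures(x, t_new)
            Q_hist[k + 1] = x[c.nf: c.nf + c.nb]
            V_hist[k + 1] = x[c.nf + c.nb:]
        cycles += 1
        end = x.copy()
        if prev_end is not None:
            denom = np.linalg.norm(end) + 1e-12
            periodicity = float(np.linalg.norm(end - prev_end) / denom)
            if periodicity < periodicity_tol:
                prev_end = end
                break
        prev_end = end

    return SimulationResult(
        compiled=c, time=times, P=P_hist, Q_branch=Q_hist, V_chamber=V_hist,
        cycles_run=cycles, converged=periodicity < periodicity_tol,
        periodicity=periodicity, final_state=x.copy(),
    )


def _step(c: _Compiled, xp: np.ndarray, t_new: float, dt: float,
          tol: float, maxiter: int, depth: int = 0) -> np.ndarray:
    tp = t_new - dt
    Pfix = c.fixed_pressures(t_new) if len(c.fixed_idx) else np.empty(0)
    Pfix_p = c.fixed_pressures(tp) if len(c.fixed_idx) else np.empty(0)
    x = xp.copy()
    res, J = _assemble(c, x, xp, t_new, tp, dt, Pfix, Pfix_p)
    norm0 = max(np.linalg.norm(res), 1.0)
    for it in range(maxiter):
        try:
            dx = np.linalg.solve(J, -res)
        except np.linalg.LinAlgError:
            dx = None
        if dx is None or not np.all(np.isfinite(dx)):
            break
        x = x + dx
        res, J = _assemble(c, x, xp, t_new, tp, dt, Pfix, Pfix_p)
        if np.linalg.norm(res) < tol * norm0 or np.linalg.norm(dx) < 1e-12 * (
                np.linalg.norm(x) + 1.0):
            return x
    # Newton failed: halve the step
    if depth >= 4:
        raise SolverError(
            f"Newton failed at t={t_new:.5f} (residual {np.linalg.norm(res):.3e})"
        )
    xm = _step(c, xp, t_new - dt / 2, dt / 2, tol, maxiter, depth + 1)
    return _step(c, xm, t_new, dt / 2, tol, maxiter, depth + 1)


# ---------------------------------------------------------------------------
# steady solver
# ---------------------------------------------------------------------------


@dataclass
class SteadyResult:
    pressures: Dict[str, float]
    flows: Dict[int, float]  # element index -> flow n1->n2

    def mean_pressure(self, name: str) -> float:
        return self.pressures[name]

    def element_flow(self, net: Network0D, elem) -> float:
        return self.flows[id(elem)]


def steady_solve(net: Network0D) -> SteadyResult:
    """Linear solve of the resistive skeleton.

    Capacitors are open circuits, vessel-branch inductances are shorts
    (the branch reduces to its resistance), valves conduct at R_open, and
    flow sources use their time-average over one period.  Chambers are not
    supported.  Exact for pure-resistor networks.
    """
    if net.chambers:
        raise SolverError("steady_solve does not support heart chambers")
    c = _Compiled(net)
    c.refresh_values()
    if c.nf == 0:
        raise SolverError("no free nodes")
    rows, cols, vals = [], [], []
    row = c.row_of_node
    t_samples = np.linspace(0.0, net.period, 33)

    def fixed_P(i):
        v = net.fixed[c.names[i]]
        if callable(v):
            return float(np.mean([v(t) for t in t_samples]))
        return float(v)

    conduct = []
    for e in net.elements:
        if isinstance(e, (Resistor, VesselBranch)):
            conduct.append((c.node_index[e.n1], c.node_index[e.n2], 1.0 / e.R, e))
        elif isinstance(e, Valve):
            conduct.append((c.node_index[e.n1], c.node_index[e.n2], 1.0 / e.R_open, e))

    # restrict unknowns to conductively connected free nodes; nodes that only
    # anchor capacitors (e.g. intramyocardial references) have no steady state
    active = set()
    for n1, n2, _, _ in conduct:
        active.add(n1)
        active.add(n2)
    for e in net.elements:
        if isinstance(e, FlowSource):
            active.add(c.node_index[e.n1])
            active.add(c.node_index[e.n2])
    row = row.copy()
    inactive = [i for i in c.free_idx if i not in active]
    for i in inactive:
        row[i] = -2  # excluded
    kept = [i for i in c.free_idx if row[i] >= 0]
    remap = -np.ones(c.n_nodes, dtype=int)
    for new, i in enumerate(kept):
        remap[i] = new
    row = np.where(row >= 0, remap, row)
    nf = len(kept)
    rhs = np.zeros(nf)

    for n1, n2, g, _ in conduct:
        r1, r2 = row[n1], row[n2]
        if r1 >= 0:
            rows.append(r1); cols.append(r1); vals.append(g)
            if r2 >= 0:
                rows.append(r1); cols.append(r2); vals.append(-g)
            else:
                rhs[r1] += g * fixed_P(n2)
        if r2 >= 0:
            rows.append(r2); cols.append(r2); vals.append(g)
            if r1 >= 0:
                rows.append(r2); cols.append(r1); vals.append(-g)
            else:
                rhs[r2] += g * fixed_P(n1)

    for e in net.elements:
        if isinstance(e, FlowSource):
            q = e.q
            if callable(q):
                q = float(np.mean([e.q(t) for t in t_samples]))
            n1, n2 = c.node_index[e.n1], c.node_index[e.n2]
            if row[n1] >= 0:
                rhs[row[n1]] -= q
            if row[n2] >= 0:
                rhs[row[n2]] += q

    G = sp.csc_matrix((vals, (rows, cols)), shape=(nf, nf))
    try:
        p_free = spla.spsolve(G, rhs)
    except Exception as exc:  # pragma: no cover
        raise SolverError(f"singular resistive network: {exc}") from exc
    if not np.all(np.isfinite(p_free)):
        raise SolverError("singular resistive network (disconnected component?)")

    P = {}
    for i, name in enumerate(c.names):
        if row[i] >= 0:
            P[name] = float(p_free[row[i]])
        elif name in net.fixed:
            P[name] = fixed_P(i)
        else:
            P[name] = float("nan")  # capacitor-reference-only node
    flows = {}
    for n1, n2, g, e in conduct:
        flows[id(e)] = (P[c.names[n1]] - P[c.names[n2]]) * g
    return SteadyResult(pressures=P, flows=flows)


# ---------------------------------------------------------------------------
# FFR
# ---------------------------------------------------------------------------


def compute_ffr(result, path_nodes: Sequence[str],
                distances: Optional[Sequence[float]] = None,
                aortic_node: str = "aorta") -> "FFRProfile":
    """FFR(s) = mean pressure at each node along a root->outlet path divided
    by mean aortic pressure; s runs from 0 (ostium) to 1 (outlet).

    ``result`` may be a :class:`SimulationResult` or :class:`SteadyResult`.
    ``distances`` are cumulative path lengths used to place s; defaults to
    uniform spacing.
    """
    if len(path_nodes) < 1:
        raise ValueError("empty FFR path")
    p_ao = result.mean_pressure(aortic_node)
    p = np.array([result.mean_pressure(n) for n in path_nodes])
    if distances is None:
        s = np.linspace(0.0, 1.0, len(path_nodes))
    else:
        d = np.asarray(distances, dtype=float)
        if len(d) != len(path_nodes) or np.any(np.diff(d) < 0):
            raise ValueError("distances must be non-decreasing, one per node")
        s = (d - d[0]) / max(d[-1] - d[0], 1e-12)
    return FFRProfile(s=s, ffr=p / p_ao)


@dataclass
class FFRProfile:
    s: np.ndarray
    ffr: np.ndarray

    @property
    def min_ffr(self) -> float:
        return float(self.ffr.min())

    @property
    def ischemic(self) -> bool:
        """True when min FFR < 0.80."""
        return self.min_ffr < FFR_ISCHEMIA_THRESHOLD
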