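"""Boundary-condition personalization.

Stage 1 matches cardiac-function targets (systolic/diastolic pressure,
stroke volume, ejection fraction) by Nelder-Mead over the closed-loop
parameters.  Stage 2 matches vessel-specific flow fractions and
microvascular pressure sources, either by scaling the ~16 image-based
outlet resistances (no synthetic trees) or by the iterative
resistance-update / tree-dilation loop (with synthetic trees).  The inner
loop of both Stage-2 variants evaluates the fast steady (resistive) 0D
surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .core_model import ClinicalTargets, FluidProperties, VesselTree
from .core_model.units import barye_to_mmhg, mmhg_to_barye
from .network0d import (
    CoronaryOutletBC,
    HeartParams,
    Network0D,
    Resistor,
    SystemicParams,
    VesselBranch,
    WindkesselBC,
    assemble_closed_loop,
    attach_outlet_bcs,
    attach_windkessel,
    build_rcl_from_tree,
    segment_rcl,
    tree_node_name,
)
from .lpn_solver import SolverError, cardiac_metrics, simulate, steady_solve
from .cco_trees import apply_radius_scaling

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InitializationRules:
    """Framework initialization constants for boundary-condition estimation."""

    q_lv_coeff: float = 3.41  # Q_LV = 3.41 V_LV^0.75 [mL/min]
    q_lv_exponent: float = 0.75
    non_lv_flow_share: float = 0.2  # non-LV coronary flow = 0.2 Q_LV
    aortic_capacitance_total: float = 0.28e-3  # cm^5/dyn
    coronary_capacitance_total: float = 1e-6  # cm^5/dyn
    ra_rmu_ratio: float = 0.38
    murray_exponent: float = 2.6
    hyperemia_factor: float = 0.24
    rv_fraction: float = 0.05  # venous share of total outlet resistance

    def q_lv(self, v_lv: float) -> float:
        """Morphometric total LV flow [mL/s]."""
        return self.q_lv_coeff * v_lv**self.q_lv_exponent / 60.0


DEFAULT_RULES = InitializationRules()


def split_outlet_resistance(R_out: float,
                            rules: InitializationRules = DEFAULT_RULES
                            ) -> Tuple[float, float, float]:
    """Split a total outlet resistance into (R_a, R_mu, R_v) with
    R_a/R_mu = 0.38 and a fixed venous share."""
    R_v = rules.rv_fraction * R_out
    R_mu = (R_out - R_v) / (1.0 + rules.ra_rmu_ratio)
    R_a = rules.ra_rmu_ratio * R_mu
    return R_a, R_mu, R_v


def murray_flow_shares(diameters: Dict[int, float], lv_flags: Dict[int, bool],
                       rules: InitializationRules = DEFAULT_RULES
                       ) -> Dict[int, float]:
    """Per-outlet shares of the total coronary flow.

    Within each group (LV-perfusing / other) shares scale with d^2.6; the
    non-LV group carries 0.2 Q_LV relative to the LV group's Q_LV.
    """
    lv = [o for o in diameters if lv_flags[o]]
    other = [o for o in diameters if not lv_flags[o]]
    shares: Dict[int, float] = {}
    lv_total = 1.0 if not other else 1.0 / (1.0 + rules.non_lv_flow_share)
    other_total = 1.0 - lv_total
    for group, total in ((lv, lv_total), (other, other_total)):
        if not group:
            continue
        w = np.array([diameters[o] ** rules.murray_exponent for o in group])
        w = w / w.sum() * total
        for o, s in zip(group, w):
            shares[o] = float(s)
    return shares


def murray_outlet_resistances(diameters: Dict[int, float],
                              lv_flags: Dict[int, bool], R_cor_total: float,
                              rules: InitializationRules = DEFAULT_RULES
                              ) -> Dict[int, float]:
    """Distal resistances realizing diameter-law flow shares.

    R_i = R_cor_total / share_i, so the parallel combination equals
    R_cor_total and, with negligible upstream resistance, outlet flows are
    proportional to d^2.6 within each group.
    """
    if any(d <= 0 for d in diameters.values()):
        raise ValueError("diameters must be > 0")
    shares = murray_flow_shares(diameters, lv_flags, rules)
    return {o: R_cor_total / s for o, s in shares.items()}


def apply_hyperemia(net: Network0D, factor: float = None,
                    rules: InitializationRules = DEFAULT_RULES) -> Network0D:
    """Scale every coronary outlet's R_a, R_mu, R_v by ``factor``
    (default 0.24).  Aortic Windkessels are untouched.  Applying the
    hyperemic factor twice raises; the inverse factor clears the state."""
    if factor is None:
        factor = rules.hyperemia_factor
    if factor <= 0:
        raise ValueError("hyperemia factor must be > 0")
    if factor < 1.0 and net.hyperemic:
        raise ValueError("network is already hyperemic (double application)")
    for h in net.outlet_blocks.values():
        h.r_a.R *= factor
        h.r_mu.R *= factor
        h.r_v.R *= factor
    if factor < 1.0:
        net.hyperemic = True
    elif factor > 1.0:
        net.hyperemic = False
    return net


# ---------------------------------------------------------------------------
# Stage 1: cardiac function
# ---------------------------------------------------------------------------


@dataclass
class TuningParam:
    name: str
    lo: float
    hi: float
    init: float

    def clip(self, v: float) -> float:
        return float(min(max(v, self.lo), self.hi))


@dataclass
class Stage1Result:
    heart: HeartParams
    systemic: SystemicParams
    R_cor_total: float
    C_cor_total: float
    objective: float  # mean relative error [%]
    per_target_errors: Dict[str, float]  # [%]
    metrics: dict
    trace: List[Tuple[int, float]]
    n_evals: int
    # cycle-averaged observables used downstream by Stage 2
    mean_aortic_pressure: float = 0.0  # [dyn/cm^2]
    mean_venous_pressure: float = 0.0  # [dyn/cm^2]


def default_param_spec(targets: ClinicalTargets,
                       rules: InitializationRules = DEFAULT_RULES
                       ) -> List[TuningParam]:
    """Data-driven Stage-1 parameter list.

    Covers, in role, the closed-loop quantities the personalization
    estimates: four-chamber elastances, ventricular activation timing,
    pulmonary R/C, intramyocardial pressure scale, total aortic and
    coronary distal resistance and capacitance, and the stressed venous
    volume (preload).
    """
    mmHg = mmhg_to_barye(1.0)
    co = targets.cardiac_output_mls  # mL/s
    p_mean = mmhg_to_barye(targets.mean_pressure)
    r_total = p_mean / co
    # coronary flow scale: roughly 4-5% of cardiac output
    r_cor = p_mean / (0.045 * co)
    spec = [
        TuningParam("E_max_lv", 0.8 * mmHg, 8.0 * mmHg, 2.6 * mmHg),
        TuningParam("E_min_lv", 0.02 * mmHg, 0.7 * mmHg, 0.07 * mmHg),
        TuningParam("E_max_la", 0.08 * mmHg, 0.8 * mmHg, 0.25 * mmHg),
        TuningParam("E_min_la", 0.05 * mmHg, 0.5 * mmHg, 0.15 * mmHg),
        TuningParam("E_max_rv", 0.2 * mmHg, 2.0 * mmHg, 0.65 * mmHg),
        TuningParam("E_min_rv", 0.015 * mmHg, 0.25 * mmHg, 0.045 * mmHg),
        TuningParam("E_max_ra", 0.06 * mmHg, 0.6 * mmHg, 0.20 * mmHg),
        TuningParam("E_min_ra", 0.04 * mmHg, 0.4 * mmHg, 0.12 * mmHg),
        TuningParam("V0_lv", 0.0, 30.0, 10.0),
        TuningParam("t_on_vent", 0.06, 0.30, 0.16),
        TuningParam("dur_vent", 0.25, 0.55, 0.40),
        TuningParam("dur_atria", 0.12, 0.40, 0.25),
        TuningParam("R_pulm", 30.0, 600.0, 120.0),
        TuningParam("C_pulm", 5e-4, 2e-2, 4e-3),
        TuningParam("im_scale_left", 0.4, 1.5, 1.0),
        TuningParam("R_aortic_wk_dist", 0.3 * r_total, 4.0 * r_total, max(r_total - 150.0, 200.0)),
        TuningParam("C_aortic_wk", 0.5 * rules.aortic_capacitance_total,
                    8.0 * rules.aortic_capacitance_total, rules.aortic_capacitance_total),
        TuningParam("C_aorta", 2e-4, 5e-3, 1e-3),
        TuningParam("R_cor_total", 0.25 * r_cor, 4.0 * r_cor, r_cor),
        TuningParam("C_cor_total", 0.2e-6, 5e-6, rules.coronary_capacitance_total),
        TuningParam("P_init_ven", 2.0 * mmHg, 30.0 * mmHg, 12.0 * mmHg),
    ]
    return spec


_HEART_FIELDS = {f for f in HeartParams.__dataclass_fields__}
_SYS_FIELDS = {f for f in SystemicParams.__dataclass_fields__}


def _build_condensed(values: Dict[str, float], targets: ClinicalTargets,
                     rules: InitializationRules) -> Network0D:
    heart = HeartParams(period=60.0 / targets.heart_rate)
    systemic = SystemicParams()
    R_cor = values.get("R_cor_total", 8e4)
    C_cor = values.get("C_cor_total", rules.coronary_capacitance_total)
    for k, v in values.items():
        if k in _HEART_FIELDS:
            setattr(heart, k, v)
        elif k in _SYS_FIELDS:
            setattr(systemic, k, v)
    # keep chamber elastance pairs admissible when the optimizer crosses them
    for ch in ("lv", "la", "rv", "ra"):
        emin = getattr(heart, f"E_min_{ch}")
        emax = getattr(heart, f"E_max_{ch}")
        if emax < 1.05 * emin:
            setattr(heart, f"E_max_{ch}", 1.05 * emin)

    r_a, r_mu, r_v = split_outlet_resistance(R_cor, rules)
    bc = CoronaryOutletBC(r_a, r_mu, r_v, C_a=C_cor / 2, C_im=C_cor / 2,
                          im_ref="LV", im_scale=heart.im_scale_left,
                          distal="sysven")

    def build(net: Network0D):
        attach_windkessel(
            net, "aorta",
            WindkesselBC(systemic.R_aortic_wk_prox, systemic.C_aortic_wk,
                         systemic.R_aortic_wk_dist), tag="ao")
        attach_outlet_bcs(net, {0: "aorta"}, {0: bc})

    net = assemble_closed_loop(heart, systemic, coronary_builder=build)
    net.meta["R_cor_total"] = R_cor
    net.meta["C_cor_total"] = C_cor
    return net


def _objective_errors(metrics, targets: ClinicalTargets) -> Dict[str, float]:
    """Per-target relative errors in percent."""
    pairs = {
        "sbp": (metrics.sbp, targets.sbp),
        "dbp": (metrics.dbp, targets.dbp),
        "stroke_volume": (metrics.stroke_volume, targets.stroke_volume),
        "ejection_fraction": (metrics.ejection_fraction, targets.ejection_fraction),
    }
    if targets.edv is not None:
        pairs["edv"] = (metrics.edv, targets.edv)
    if targets.esv is not None:
        pairs["esv"] = (metrics.esv, targets.esv)
    return {k: 100.0 * abs(sim - tgt) / abs(tgt) for k, (sim, tgt) in pairs.items()}


def _calibrate_initials(x0: np.ndarray, names: List[str], lo: np.ndarray,
                        hi: np.ndarray, forward, targets: ClinicalTargets,
                        n_iter: int = 16) -> np.ndarray:
    """Multiplicative fixed-point pre-conditioning of the initial guess.

    Iterates simple physiological sensitivities: distal resistance toward
    the mean-pressure target, arterial compliance toward the pulse
    pressure, venous stressed volume toward the stroke volume, and LV
    elastances toward EF and EDV.  Greatly reduces the work left to the
    simplex search.
    """
    ix = {n: i for i, n in enumerate(names)}
    x = x0.copy()
    pp_tgt = targets.sbp - targets.dbp
    p_mean_tgt = targets.mean_pressure
    edv_tgt = targets.stroke_volume / targets.ejection_fraction
    best_x, best_err = x.copy(), np.inf
    for _ in range(n_iter):
        try:
            _, res = forward(x)
        except (SolverError, ValueError):
            break
        m = cardiac_metrics(res)
        errs = _objective_errors(m, targets)
        err = float(np.mean(list(errs.values())))
        if err < best_err:
            best_err, best_x = err, x.copy()
        if err < 1.0:
            break
        p_mean_sim = m.dbp + (m.sbp - m.dbp) / 3.0
        pp_sim = m.sbp - m.dbp

        def scale(name, factor, power=1.0):
            if name in ix:
                x[ix[name]] = np.clip(x[ix[name]] * factor**power,
                                      lo[ix[name]], hi[ix[name]])

        scale("R_aortic_wk_dist", p_mean_tgt / p_mean_sim, 1.0)
        scale("C_aorta", pp_sim / pp_tgt, 0.7)
        scale("C_aortic_wk", pp_sim / pp_tgt, 0.3)
        scale("P_init_ven", targets.stroke_volume / m.stroke_volume, 0.9)
        scale("E_max_lv", targets.ejection_fraction / m.ejection_fraction, 1.4)
        scale("E_min_lv", m.edv / edv_tgt, 0.7)
        if "V0_lv" in ix:  # shift unstressed volume toward the ESV target
            esv_tgt = edv_tgt - targets.stroke_volume
            x[ix["V0_lv"]] = np.clip(
                x[ix["V0_lv"]] + 0.7 * (esv_tgt - m.esv),
                lo[ix["V0_lv"]], hi[ix["V0_lv"]])
    return best_x


def stage1_tune(targets: ClinicalTargets,
                param_spec: Optional[List[TuningParam]] = None,
                rules: InitializationRules = DEFAULT_RULES,
                nm_tol: float = 0.1, nm_maxiter: int = 200,
                nm_step_fraction: float = 0.1, nm_restarts: int = 50,
                stop_objective: float = 0.5, stall_restarts: int = 3,
                seed: int = 0,
                tuning_dt_divisor: int = 250, tuning_cycles: int = 8,
                final_dt_divisor: int = 1000) -> Stage1Result:
    """Nelder-Mead fit of the closed-loop model to cardiac-function targets.

    Objective: unweighted mean of per-target relative errors in percent.
    The stated optimizer settings are used (tolerance 0.1, up to 200
    iterations, initial step 0.1 of each parameter range, up to 50
    restarts with seeded jitter of the incumbent); restarts terminate
    early once the objective falls below ``stop_objective`` percent or
    stalls for ``stall_restarts`` consecutive restarts.
    """
    spec = param_spec or default_param_spec(targets, rules)
    names = [p.name for p in spec]
    lo = np.array([p.lo for p in spec])
    hi = np.array([p.hi for p in spec])
    x0 = np.array([p.init for p in spec])
    rng = np.random.default_rng(seed)
    T = 60.0 / targets.heart_rate

    state = {"warm": None, "evals": 0, "trace": []}

    def forward(x: np.ndarray, fine: bool = False):
        values = dict(zip(names, np.clip(x, lo, hi)))
        net = _build_condensed(values, targets, rules)
        dt = T / (final_dt_divisor if fine else tuning_dt_divisor)
        cycles = 14 if fine else tuning_cycles
        tol = 1e-3 if fine else 2e-3
        res = simulate(net, n_cycles_max=cycles, dt=dt, periodicity_tol=tol,
                       x0=None if fine else state["warm"])
        return net, res

    def objective(x: np.ndarray) -> float:
        state["evals"] += 1
        try:
            net, res = forward(x)
        except (SolverError, ValueError):
            return 1e4
        state["warm"] = res.final_state
        m = cardiac_metrics(res)
        errs = _objective_errors(m, targets)
        val = float(np.mean(list(errs.values())))
        state["trace"].append((state["evals"], val))
        return val

    x0 = _calibrate_initials(x0, names, lo, hi, forward, targets)
    best_x, best_f = x0.copy(), objective(x0)
    incumbent = x0.copy()
    stalled = 0
    for restart in range(nm_restarts):
        step = nm_step_fraction * (hi - lo)
        simplex = [incumbent]
        for k in range(len(spec)):
            v = incumbent.copy()
            v[k] = np.clip(v[k] + step[k] * (1 if v[k] + step[k] <= hi[k] else -1),
                           lo[k], hi[k])
            simplex.append(v)
        res = minimize(objective, incumbent, method="Nelder-Mead",
                       bounds=list(zip(lo, hi)),
                       options={"maxiter": nm_maxiter, "fatol": nm_tol,
                                "xatol": 1e-12,
                                "initial_simplex": np.array(simplex)})
        if res.fun < best_f - nm_tol:
            stalled = 0
        else:
            stalled += 1
        if res.fun < best_f:
            best_f, best_x = float(res.fun), np.asarray(res.x)
        if best_f <= stop_objective or stalled >= stall_restarts:
            break
        incumbent = np.clip(
            best_x + rng.normal(0.0, 0.05, size=len(spec)) * (hi - lo), lo, hi)

    # final verification at fine resolution
    values = dict(zip(names, np.clip(best_x, lo, hi)))
    net, res = forward(best_x, fine=True)
    m = cardiac_metrics(res)
    errs = _objective_errors(m, targets)
    heart = net.meta["heart"]
    systemic = net.meta["systemic"]
    return Stage1Result(
        heart=heart, systemic=systemic,
        R_cor_total=net.meta["R_cor_total"], C_cor_total=net.meta["C_cor_total"],
        objective=float(np.mean(list(errs.values()))),
        per_target_errors=errs, metrics=m.to_dict(), trace=state["trace"],
        n_evals=state["evals"],
        mean_aortic_pressure=res.mean_pressure("aorta"),
        mean_venous_pressure=res.mean_pressure("sysven"),
    )


# ---------------------------------------------------------------------------
# flow targets
# ---------------------------------------------------------------------------


@dataclass
class FlowTargets:
    """Per-outlet required flows [mL/s] and pressure sources [dyn/cm^2]."""

    q_reqd: Dict[int, float]
    p_src: Dict[int, float]
    q_lv: float
    pbar_src: float
    mode: str


def build_flow_targets(tmap, q_lv: float, v_lv: float, pbar_src: float,
                       mode: str = "mpi",
                       diameters: Optional[Dict[int, float]] = None,
                       rules: InitializationRules = DEFAULT_RULES) -> FlowTargets:
    """Required per-outlet flow and microvascular source pressure.

    mpi mode: Q_reqd^i = fraction_i x Q_LV from the territory MBF
    integrals and p_src^i from the territory-MBF inversion
    p_src^i = MBF_{V_i}/(beta_src V_i) + p_cap.
    murray mode: shares proportional to d^2.6; p_src uniform at pbar_src.
    """
    from .darcy import required_sources

    if mode == "mpi":
        fracs = tmap.fractions
        q_reqd = {sid: float(f * q_lv) for sid, f in zip(tmap.outlet_ids, fracs)}
        # scale territory flows to the target q_lv before inverting
        scaled = replace_flows(tmap, q_lv)
        p_src = required_sources(scaled, q_lv, v_lv, pbar_src)
    elif mode == "murray":
        if diameters is None:
            raise ValueError("murray mode requires outlet diameters")
        w = np.array([diameters[sid] ** rules.murray_exponent
                      for sid in tmap.outlet_ids])
        w = w / w.sum()
        q_reqd = {sid: float(f * q_lv) for sid, f in zip(tmap.outlet_ids, w)}
        p_src = {sid: pbar_src for sid in tmap.outlet_ids}
    else:
        raise ValueError(f"unknown target mode {mode!r}")
    return FlowTargets(q_reqd=q_reqd, p_src=p_src, q_lv=q_lv,
                       pbar_src=pbar_src, mode=mode)


def initial_pbar_src(model: "SteadyCoronaryModel", tmap,
                     rules: InitializationRules = DEFAULT_RULES) -> float:
    """Volume-weighted mean microvascular pressure of the current model.

    Serves as the guess for the spatially averaged pressure source needed
    by the conductance parameterization before the sources are known.
    """
    st = model.solve()
    lv = model.lv_outlet_keys()
    pos = {k: i for i, k in enumerate(tmap.outlet_ids)}
    num = den = 0.0
    p_min = np.inf
    for k in lv:
        r_a = split_outlet_resistance(model.R_out[k], rules)[0]
        p_mu = st.P[k] - st.Q[k] * r_a
        v = tmap.volumes[pos[k]]
        num += p_mu * v
        den += v
        p_min = min(p_min, st.P[k])
    pbar = num / den
    # feasibility cap: the highest required source pressure
    # p_src = p_cap + (pbar - p_cap) * g, with g the territory MBF-density
    # ratio, must stay below the lowest outlet pressure (sources cannot
    # exceed the pressure feeding them)
    p_cap = mmhg_to_barye(15.0)
    fr = tmap.fractions
    g_max = float(np.max(fr * tmap.total_volume / tmap.volumes))
    cap = p_cap + 0.6 * (p_min - p_cap) / g_max
    return float(min(pbar, cap))


def replace_flows(tmap, q_lv: float):
    """Copy of a territory map with flows rescaled to sum to q_lv."""
    import copy

    out = copy.copy(tmap)
    out.flows = tmap.flows * (q_lv / tmap.flows.sum())
    return out


# ---------------------------------------------------------------------------
# steady coronary surrogate shared by the Stage-2 variants
# ---------------------------------------------------------------------------


@dataclass
class SteadyCoronaryModel:
    """Resistive hyperemic surrogate of the coronary model.

    Epicardial tree (plus optional synthetic trees appended at each
    LV-perfusing epicardial outlet) driven by a fixed mean aortic
    pressure, draining through per-outlet distal resistances to a fixed
    back pressure.
    """

    epi_tree: VesselTree
    fluid: FluidProperties
    p_aorta: float  # [dyn/cm^2]
    p_distal: float  # [dyn/cm^2]
    R_out: Dict[object, float]  # outlet key -> total distal resistance
    synthetic: Dict[int, VesselTree] = field(default_factory=dict)
    aortic_outlet: Optional[int] = None  # epicardial leaf excluded from outlets

    def outlet_keys(self) -> List[object]:
        keys: List[object] = []
        for sid in self.epi_tree.outlet_ids:
            if sid == self.aortic_outlet:
                continue
            if sid in self.synthetic:
                keys.extend((sid, t) for t in self.synthetic[sid].outlet_ids)
            else:
                keys.append(sid)
        return keys

    def lv_outlet_keys(self) -> List[object]:
        out = []
        for k in self.outlet_keys():
            epi = k[0] if isinstance(k, tuple) else k
            if isinstance(k, tuple) or self.epi_tree.segments[epi].perfuses_lv:
                out.append(k)
        return out

    def _outlet_node(self, key) -> str:
        if isinstance(key, tuple):
            return tree_node_name(f"syn{key[0]}", key[1])
        return tree_node_name("epi", key)

    def build(self) -> Network0D:
        net = Network0D()
        net.fix_pressure("aorta", self.p_aorta)
        net.fix_pressure("dist", self.p_distal)
        build_rcl_from_tree(net, self.epi_tree, self.fluid, "aorta", "epi",
                            include_capacitors=False)
        for epi_oid, stree in self.synthetic.items():
            build_rcl_from_tree(net, stree, self.fluid,
                                tree_node_name("epi", epi_oid), f"syn{epi_oid}",
                                include_capacitors=False)
        for key in self.outlet_keys():
            net.add(Resistor(self._outlet_node(key), "dist", self.R_out[key],
                             label=f"out:{key}"))
        if self.aortic_outlet is not None:
            net.add(Resistor(tree_node_name("epi", self.aortic_outlet), "dist",
                             self.R_out[self.aortic_outlet], label="out:aorta"))
        return net

    def solve(self) -> "SteadyOutletState":
        net = self.build()
        res = steady_solve(net)
        P, Q, P_epi = {}, {}, {}
        for key in self.outlet_keys():
            node = self._outlet_node(key)
            p_i = res.pressures[node]
            q_i = (p_i - self.p_distal) / self.R_out[key]
            P[key], Q[key] = p_i, q_i
            epi = key[0] if isinstance(key, tuple) else key
            P_epi[key] = res.pressures[tree_node_name("epi", epi)]
        return SteadyOutletState(P=P, Q=Q, P_epi=P_epi, p_aorta=self.p_aorta,
                                 result=res)


@dataclass
class SteadyOutletState:
    P: Dict[object, float]
    Q: Dict[object, float]
    P_epi: Dict[object, float]
    p_aorta: float
    result: object

    def r_path(self, key) -> float:
        return (self.p_aorta - self.P[key]) / self.Q[key]

    def r_path_syn(self, key) -> float:
        return (self.P_epi[key] - self.P[key]) / self.Q[key]


def parallel_resistance(values: Sequence[float]) -> float:
    values = np.asarray(list(values), dtype=float)
    return 1.0 / np.sum(1.0 / values)


# ---------------------------------------------------------------------------
# Stage 2 without synthetic trees
# ---------------------------------------------------------------------------


@dataclass
class Stage2Result:
    R_out: Dict[object, float]
    R_a: Dict[object, float]
    R_mu: Dict[object, float]
    R_v: Dict[object, float]
    flow_error: float  # mean relative flow-fraction error (fraction, not %)
    pressure_error: float  # mean relative P_mu-vs-p_src error after updates
    fractions: Dict[object, float]
    trace: List[dict]


def _fraction_error(model: SteadyCoronaryModel, targets: FlowTargets) -> Tuple[float, Dict]:
    state = model.solve()
    lv = model.lv_outlet_keys()
    q = np.array([state.Q[k] for k in lv])
    f_sim = q / q.sum()
    f_tgt = np.array([targets.q_reqd[k] for k in lv])
    f_tgt = f_tgt / f_tgt.sum()
    err = float(np.mean(np.abs(f_sim - f_tgt) / f_tgt))
    return err, dict(zip(lv, f_sim))


def stage2_no_trees(model: SteadyCoronaryModel, targets: FlowTargets,
                    rules: InitializationRules = DEFAULT_RULES,
                    nm_maxiter: int = 200, nm_restarts: int = 50,
                    nm_tol: float = 0.1, stop_objective: float = 0.005,
                    seed: int = 0, n_ra_updates: int = 2) -> Stage2Result:
    """Scale-factor optimization of the image-based outlet resistances.

    Nelder-Mead over per-outlet scale factors in [0.5, 2.0], renormalized
    each evaluation to preserve the total parallel outlet resistance,
    minimizing the mean relative flow-fraction error; followed by two
    direct R_a/R_mu updates matching the microvascular pressure sources
    (R_a^i = (P^i - p_src^i)/Q^i with R_a+R_mu+R_v held fixed).
    """
    lv = model.lv_outlet_keys()
    base_R = {k: model.R_out[k] for k in model.outlet_keys()}
    R_total0 = parallel_resistance(base_R.values())
    rng = np.random.default_rng(seed)
    trace: List[dict] = []

    def apply_scales(s: np.ndarray) -> None:
        for k, sk in zip(lv, s):
            model.R_out[k] = base_R[k] * sk
        # renormalize over ALL outlets to preserve the stage-1 total
        R_now = parallel_resistance(model.R_out[k] for k in model.outlet_keys())
        c = R_total0 / R_now
        for k in model.outlet_keys():
            model.R_out[k] *= c

    def objective(s: np.ndarray) -> float:
        s = np.clip(s, 0.5, 2.0)
        apply_scales(s)
        err, _ = _fraction_error(model, targets)
        trace.append({"stage": "flow-nm", "objective": err})
        return err

    x0 = np.ones(len(lv))
    best_x, best_f = x0.copy(), objective(x0)
    incumbent = x0.copy()
    stalled = 0
    for restart in range(nm_restarts):
        simplex = [incumbent]
        for k in range(len(lv)):
            v = incumbent.copy()
            v[k] = np.clip(v[k] + 0.1 * 1.5, 0.5, 2.0)
            simplex.append(v)
        res = minimize(objective, incumbent, method="Nelder-Mead",
                       bounds=[(0.5, 2.0)] * len(lv),
                       options={"maxiter": nm_maxiter, "fatol": 1e-5,
                                "xatol": 1e-10,
                                "initial_simplex": np.array(simplex)})
        improved = res.fun < best_f - 1e-5
        if res.fun < best_f:
            best_f, best_x = float(res.fun), np.asarray(res.x)
        stalled = 0 if improved else stalled + 1
        if best_f <= stop_objective or stalled >= 2:
            break
        incumbent = np.clip(best_x + rng.normal(0, 0.05, len(lv)), 0.5, 2.0)

    apply_scales(np.clip(best_x, 0.5, 2.0))
    flow_err, fractions = _fraction_error(model, targets)

    # direct R_a / R_mu updates toward the required microvascular sources
    R_a, R_mu, R_v = {}, {}, {}
    for k in model.outlet_keys():
        R_a[k], R_mu[k], R_v[k] = split_outlet_resistance(model.R_out[k], rules)
    p_err = np.inf
    for it in range(n_ra_updates):
        state = model.solve()
        errs = []
        for k in lv:
            p_src = targets.p_src[k]
            ra_req = (state.P[k] - p_src) / state.Q[k]
            hi = 0.95 * (R_a[k] + R_mu[k])
            ra_new = min(max(ra_req, 0.01 * hi), hi)
            if ra_new != ra_req:
                log.warning("outlet %s: R_a update clamped", k)
            R_mu[k] = (R_a[k] + R_mu[k]) - ra_new
            R_a[k] = ra_new
            p_mu = state.P[k] - state.Q[k] * R_a[k]
            errs.append(abs(p_mu - p_src) / p_src)
        p_err = float(np.mean(errs))
        trace.append({"stage": f"ra-update-{it + 1}", "pressure_error": p_err})

    return Stage2Result(R_out=dict(model.R_out), R_a=R_a, R_mu=R_mu, R_v=R_v,
                        flow_error=flow_err, pressure_error=p_err,
                        fractions=fractions, trace=trace)


# ---------------------------------------------------------------------------
# Stage 2 with synthetic trees
# ---------------------------------------------------------------------------


@dataclass
class TuningState:
    """Iteration state of the with-trees personalization loop."""

    q_reqd: Dict[object, float]
    p_src: Dict[object, float]
    eps_flow: float = np.inf
    eps_pressure: float = np.inf
    outer_iterations: int = 0
    converged: bool = False
    log: List[dict] = field(default_factory=list)


def stage2_with_trees(model: SteadyCoronaryModel, targets: FlowTargets,
                      R_tot: float, tol: float = 0.05, max_outer: int = 30,
                      max_flow_subiter: int = 20,
                      rules: InitializationRules = DEFAULT_RULES,
                      margin_fraction: float = 0.05) -> TuningState:
    """Iterative flow/pressure personalization with tree dilation.

    Flow step: from a steady hyperemic solve compute
    R_path^i = (P_aorta - P^i)/Q^i and the required distal resistance
    R_out,reqd^i = R_tot Q_LV / Q_reqd^i - R_path^i.  Where that is below
    a positive margin, reduce the synthetic path resistance to
    R~_path,syn^i and dilate by alpha^i = (R_path,syn/R~_path,syn)^(1/4).
    Repeat until all outlet resistances are physiological and
    eps_flow <= tol.

    Pressure step: P_reqd^i = p_src^i + Q_reqd^i R_a^i;
    R_path,reqd^i = (P_aorta - P_reqd^i)/Q_reqd^i; move the synthetic
    share of the path resistance toward it (dilating or constricting) and
    return to the flow step until eps_pressure <= tol as well.
    """
    lv = model.lv_outlet_keys()
    q_reqd = {k: targets.q_reqd[k] for k in lv}
    # targets are relative (fractions of total LV flow); rescale the total so
    # the flow targets are consistent with R_tot and the mean driving pressure
    q_consistent = (model.p_aorta - model.p_distal) / R_tot
    scale = q_consistent / sum(q_reqd.values())
    q_reqd = {k: q * scale for k, q in q_reqd.items()}
    q_lv = sum(q_reqd.values())
    state = TuningState(q_reqd=q_reqd, p_src=dict(targets.p_src))

    def r_a_of(key) -> float:
        return split_outlet_resistance(model.R_out[key], rules)[0]

    def dilate(alphas: Dict[int, Dict[int, float]]) -> None:
        """Apply per-synthetic-outlet radius scale factors tree by tree."""
        for epi_oid, scales in alphas.items():
            stree = model.synthetic[epi_oid]
            full = {sid: scales.get(sid, 1.0) for sid in stree.outlet_ids}
            model.synthetic[epi_oid] = apply_radius_scaling(stree, full)

    def flow_step() -> float:
        mean_R_out = float(np.mean([model.R_out[k] for k in lv]))
        margin = margin_fraction * mean_R_out
        for sub in range(max_flow_subiter):
            st = model.solve()
            alphas: Dict[int, Dict[int, float]] = {}
            for k in lv:
                r_path = st.r_path(k)
                r_reqd = R_tot * q_lv / q_reqd[k] - r_path
                if r_reqd < margin:
                    r_syn = st.r_path_syn(k)
                    r_syn_tilde = r_syn - (margin - r_reqd)
                    if r_syn_tilde <= 0:
                        raise RuntimeError(
                            f"outlet {k}: infeasible synthetic path resistance "
                            f"(required {r_syn_tilde:.3g})")
                    alpha = (r_syn / r_syn_tilde) ** 0.25
                    alphas.setdefault(k[0], {})[k[1]] = alpha
                    r_reqd = margin
                model.R_out[k] = r_reqd
            if alphas:
                dilate(alphas)
            st = model.solve()
            q = np.array([st.Q[k] for k in lv])
            qr = np.array([q_reqd[k] for k in lv])
            eps = float(np.mean(np.abs(q - qr) / qr))
            state.log.append({"step": "flow", "sub": sub, "eps_flow": eps})
            if eps <= tol and not alphas:
                return eps
        return eps

    eps_flow = np.inf
    eps_pressure = np.inf
    for outer in range(max_outer):
        state.outer_iterations = outer + 1
        eps_flow = flow_step()
        st = model.solve()
        p_reqd = {k: targets.p_src[k] + q_reqd[k] * r_a_of(k) for k in lv}
        p = np.array([st.P[k] for k in lv])
        pr = np.array([p_reqd[k] for k in lv])
        eps_pressure = float(np.mean(np.abs(p - pr) / pr))
        state.log.append({"step": "pressure", "outer": outer,
                          "eps_flow": eps_flow, "eps_pressure": eps_pressure})
        if eps_flow <= tol and eps_pressure <= tol:
            state.converged = True
            break
        # constrict/dilate toward the required path resistance; the per-pass
        # dilation is clamped so outlets whose requirement is momentarily
        # infeasible (shared upstream drops still equilibrating) approach it
        # gradually instead of aborting
        alphas: Dict[int, Dict[int, float]] = {}
        n_infeasible = 0
        for k in lv:
            r_path_reqd = (model.p_aorta - p_reqd[k]) / q_reqd[k]
            r_path = st.r_path(k)
            r_syn = st.r_path_syn(k)
            r_syn_tilde = r_path_reqd - (r_path - r_syn)
            if r_syn_tilde <= 0.05 * r_syn:
                n_infeasible += 1
                log.debug("outlet %s: required synthetic path resistance "
                          "%.3g clamped", k, r_syn_tilde)
                r_syn_tilde = 0.05 * r_syn
            alpha = (r_syn / r_syn_tilde) ** 0.25
            alphas.setdefault(k[0], {})[k[1]] = alpha
        if n_infeasible == len(lv):
            raise RuntimeError(
                "infeasible pressure targets at every synthetic outlet")
        dilate(alphas)

    state.eps_flow = eps_flow
    state.eps_pressure = eps_pressure
    return state
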