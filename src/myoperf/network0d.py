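"""0D (lumped-parameter) circuit surrogates of the coronary circulation.

A :class:`Network0D` is a named-node circuit holding resistors, RL vessel
branches, capacitors (optionally referenced to a scaled chamber pressure,
which models intramyocardial squeeze), smooth-diode valves, flow sources
and time-varying-elastance heart chambers.  Vessel trees are distilled
into RCL chains by Poiseuille/linearization formulas; coronary outlets get
R_a - C_a - R_mu - C_im(P_im) - R_v boundary blocks; the closed loop adds
four chambers, valves, a systemic Windkessel and a pulmonary RC.

All values are CGS: dyn.s/cm^5, cm^5/dyn, dyn.s^2/cm^5, dyn/cm^2, mL/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Union

import numpy as np

from .core_model import FluidProperties, VesselTree
from .core_model.units import mmhg_to_barye

# ---------------------------------------------------------------------------
# elements
# ---------------------------------------------------------------------------


@dataclass
class Resistor:
    n1: str
    n2: str
    R: float
    label: str = ""


@dataclass
class VesselBranch:
    """Series RL through-branch with its own flow state:
    L dQ/dt = P1 - P2 - R Q."""

    n1: str
    n2: str
    R: float
    L: float
    label: str = ""


@dataclass
class Capacitor:
    """Compliance from ``node`` to a reference pressure.

    The reference is ``ref_scale * P(ref_node)`` (0 if ``ref_node`` is
    None).  The charging current leaves ``node`` only; the reference is a
    pure pressure source (used for intramyocardial pressure coupling).
    """

    node: str
    C: float
    ref_node: Optional[str] = None
    ref_scale: float = 1.0
    label: str = ""


@dataclass
class Valve:
    """Smooth diode: conductance blends between 1/R_open (forward) and
    1/R_leak (reverse) over a pressure width ``w``."""

    n1: str
    n2: str
    R_open: float = 8.0
    R_leak: float = 1e8
    w: float = 400.0  # dyn/cm^2 (~0.3 mmHg)
    label: str = ""


@dataclass
class FlowSource:
    """Prescribed flow from n1 to n2; q is a constant or callable(t)."""

    n1: str
    n2: str
    q: Union[float, Callable[[float], float]]
    label: str = ""


@dataclass
class HeartChamber:
    """Time-varying elastance chamber: P = E(t) (V - V0).

    E(t) = E_min + (E_max - E_min) * a(t) with a raised-cosine activation
    of the given onset and duration (periodic in the cardiac cycle).
    Elastances in dyn/cm^2/mL, volumes in mL, times in s.
    """

    node: str
    E_max: float
    E_min: float
    V0: float
    t_on: float
    duration: float
    V_init: float = 0.0

    def __post_init__(self):
        if not (self.E_max >= self.E_min > 0):
            raise ValueError(f"chamber {self.node}: require E_max >= E_min > 0")

    def activation(self, t: float, period: float) -> float:
        tau = (t - self.t_on) % period
        if tau < self.duration:
            return 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / self.duration))
        return 0.0

    def elastance(self, t: float, period: float) -> float:
        return self.E_min + (self.E_max - self.E_min) * self.activation(t, period)


@dataclass
class CoronaryOutletBC:
    """Coronary outlet boundary block R_a - C_a - R_mu - C_im - R_v."""

    R_a: float
    R_mu: float
    R_v: float
    C_a: float = 1e-7
    C_im: float = 1e-7
    im_ref: str = "LV"  # chamber node providing intramyocardial pressure
    im_scale: float = 1.0
    distal: str = "sysven"

    def __post_init__(self):
        if min(self.R_a, self.R_mu, self.R_v) < 0 or self.total_R <= 0:
            raise ValueError("invalid coronary BC resistances")

    @property
    def total_R(self) -> float:
        return self.R_a + self.R_mu + self.R_v


@dataclass
class WindkesselBC:
    """Proximal R, compliance, distal R to a venous node."""

    R_p: float
    C: float
    R_d: float
    distal: str = "sysven"


@dataclass
class OutletHandle:
    """Handle to the circuit pieces of one coronary outlet block."""

    outlet_node: str  # P^i: pressure at the vessel outlet
    mu_node: str  # node between R_a and R_mu
    vn_node: str  # node between R_mu and R_v
    r_a: Resistor
    r_mu: Resistor
    r_v: Resistor


class Network0D:
    """Mutable named-node lumped-parameter circuit."""

    def __init__(self, period: float = 1.0):
        self.period = period
        self.elements: List[object] = []
        self.chambers: List[HeartChamber] = []
        self.fixed: Dict[str, Union[float, Callable[[float], float]]] = {}
        self.outlet_blocks: Dict[int, OutletHandle] = {}
        self.windkessels: Dict[int, WindkesselBC] = {}
        self.hyperemic: bool = False
        self.meta: dict = {}

    # -- construction -------------------------------------------------------

    def add(self, element) -> object:
        self.elements.append(element)
        return element

    def add_chamber(self, chamber: HeartChamber) -> HeartChamber:
        self.chambers.append(chamber)
        return chamber

    def fix_pressure(self, node: str, value) -> None:
        self.fixed[node] = value

    # -- queries ------------------------------------------------------------

    def node_names(self) -> List[str]:
        names: List[str] = []
        seen = set()

        def visit(n):
            if n is not None and n not in seen:
                seen.add(n)
                names.append(n)

        for e in self.elements:
            if isinstance(e, Capacitor):
                visit(e.node)
                visit(e.ref_node)
            else:
                visit(e.n1)
                visit(e.n2)
        for ch in self.chambers:
            visit(ch.node)
        for n in self.fixed:
            visit(n)
        return names

    def resistors(self) -> List[Resistor]:
        return [e for e in self.elements if isinstance(e, Resistor)]

    def branches(self) -> List[VesselBranch]:
        return [e for e in self.elements if isinstance(e, VesselBranch)]

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-serializable description (numeric fixed pressures only)."""
        elems = []
        for e in self.elements:
            d = {"kind": type(e).__name__}
            d.update({k: v for k, v in e.__dict__.items()})
            if isinstance(e, FlowSource) and callable(e.q):
                raise ValueError("cannot serialize a callable flow source")
            elems.append(d)
        for n, v in self.fixed.items():
            if callable(v):
                raise ValueError("cannot serialize a callable fixed pressure")
        return {
            "period": self.period,
            "elements": elems,
            "chambers": [dict(c.__dict__) for c in self.chambers],
            "fixed": dict(self.fixed),
            "hyperemic": self.hyperemic,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Network0D":
        kinds = {k.__name__: k for k in
                 (Resistor, VesselBranch, Capacitor, Valve, FlowSource)}
        net = cls(period=doc.get("period", 1.0))
        for d in doc["elements"]:
            d = dict(d)
            kind = kinds[d.pop("kind")]
            net.add(kind(**d))
        for d in doc.get("chambers", []):
            net.add_chamber(HeartChamber(**d))
        for n, v in doc.get("fixed", {}).items():
            net.fix_pressure(n, v)
        net.hyperemic = doc.get("hyperemic", False)
        return net


# ---------------------------------------------------------------------------
# RCL distillation of vessel trees
# ---------------------------------------------------------------------------


def segment_rcl(length: float, radius: float, fluid: FluidProperties,
                elastic_modulus: float = 1.15e7,
                wall_thickness_ratio: float = 0.1) -> tuple:
    """Poiseuille/linearized lumped values for a cylindrical segment.

    R = 8 mu l / (pi r^4), L = rho l / (pi r^2),
    C = 3 pi r^3 l / (2 E h) with wall thickness h = ratio * r.
    """
    if radius <= 0:
        raise ValueError("segment radius must be > 0")
    r4 = radius**4
    R = 8.0 * fluid.viscosity * length / (np.pi * r4)
    L = fluid.density * length / (np.pi * radius**2)
    h = wall_thickness_ratio * radius
    C = 3.0 * np.pi * radius**3 * length / (2.0 * elastic_modulus * h)
    return R, L, C


def tree_node_name(tree_tag: str, sid: int) -> str:
    return f"{tree_tag}:s{sid}"


def build_rcl_from_tree(net: Network0D, tree: VesselTree, fluid: FluidProperties,
                        inlet_node: str, tree_tag: str = "t",
                        elastic_modulus: float = 1.15e7,
                        wall_thickness_ratio: float = 0.1,
                        include_capacitors: bool = True) -> Dict[int, VesselBranch]:
    """Append the RCL representation of ``tree`` to ``net``.

    Each segment becomes a series-RL branch from its parent's distal node
    (the root connects to ``inlet_node``) to its own distal node, plus a
    wall-compliance capacitor at the distal node.  Junctions are ideal.
    Returns the per-segment branch elements (mutable, for re-tuning).
    """
    branches: Dict[int, VesselBranch] = {}
    for sid in tree.topo_order():
        s = tree.segments[sid]
        up = inlet_node if s.parent_id is None else tree_node_name(tree_tag, s.parent_id)
        dn = tree_node_name(tree_tag, sid)
        R, L, C = segment_rcl(s.length, s.radius, fluid, elastic_modulus,
                              wall_thickness_ratio)
        branches[sid] = net.add(VesselBranch(up, dn, R, L, label=f"{tree_tag}:seg{sid}"))
        if include_capacitors and C > 0:
            net.add(Capacitor(dn, C, label=f"{tree_tag}:C{sid}"))
    return branches


def update_branches_from_tree(branches: Dict[int, VesselBranch], tree: VesselTree,
                              fluid: FluidProperties) -> None:
    """Refresh branch R/L after a geometric (radius) change of the tree."""
    for sid, br in branches.items():
        s = tree.segments[sid]
        R, L, _ = segment_rcl(s.length, s.radius, fluid)
        br.R, br.L = R, L


def attach_outlet_bcs(net: Network0D, outlet_nodes: Dict[int, str],
                      bcs: Dict[int, CoronaryOutletBC]) -> Dict[int, OutletHandle]:
    """Attach a coronary boundary block at each outlet node.

    The microvascular pressure observable is
    ``P_mu^i = P^i - Q^i R_a^i`` (the pressure at the node between R_a and
    R_mu on cycle average).
    """
    missing = set(outlet_nodes) - set(bcs)
    if missing:
        raise ValueError(f"missing boundary conditions for outlets {sorted(missing)}")
    handles: Dict[int, OutletHandle] = {}
    for oid, node in outlet_nodes.items():
        bc = bcs[oid]
        mu = f"{node}:mu"
        vn = f"{node}:vn"
        r_a = net.add(Resistor(node, mu, bc.R_a, label=f"bc{oid}:Ra"))
        net.add(Capacitor(mu, bc.C_a, label=f"bc{oid}:Ca"))
        r_mu = net.add(Resistor(mu, vn, bc.R_mu, label=f"bc{oid}:Rmu"))
        net.add(Capacitor(vn, bc.C_im, ref_node=bc.im_ref, ref_scale=bc.im_scale,
                          label=f"bc{oid}:Cim"))
        r_v = net.add(Resistor(vn, bc.distal, bc.R_v, label=f"bc{oid}:Rv"))
        handles[oid] = OutletHandle(node, mu, vn, r_a, r_mu, r_v)
        net.outlet_blocks[oid] = handles[oid]
    return handles


def attach_windkessel(net: Network0D, node: str, wk: WindkesselBC, tag: str) -> None:
    mid = f"{tag}:wk"
    net.add(Resistor(node, mid, wk.R_p, label=f"{tag}:Rp"))
    net.add(Capacitor(mid, wk.C, label=f"{tag}:Cwk"))
    net.add(Resistor(mid, wk.distal, wk.R_d, label=f"{tag}:Rd"))


# ---------------------------------------------------------------------------
# closed loop
# ---------------------------------------------------------------------------


@dataclass
class HeartParams:
    """Four-chamber elastance parameters (mmHg/mL converted on build) plus
    activation timing, for one cardiac period T."""

    period: float = 1.0
    # elastances in dyn/cm^2/mL
    E_max_lv: float = 2.6 * 1333.22
    E_min_lv: float = 0.07 * 1333.22
    E_max_la: float = 0.25 * 1333.22
    E_min_la: float = 0.15 * 1333.22
    E_max_rv: float = 0.65 * 1333.22
    E_min_rv: float = 0.045 * 1333.22
    E_max_ra: float = 0.20 * 1333.22
    E_min_ra: float = 0.12 * 1333.22
    V0_lv: float = 10.0
    V0_la: float = 5.0
    V0_rv: float = 15.0
    V0_ra: float = 8.0
    t_on_atria: float = 0.0
    dur_atria: float = 0.25
    t_on_vent: float = 0.16
    dur_vent: float = 0.40
    valve_R: float = 6.0
    valve_R_leak: float = 1e8
    im_scale_left: float = 1.0
    im_scale_right: float = 0.5


@dataclass
class SystemicParams:
    """Systemic + pulmonary lumped parameters (CGS)."""

    C_aorta: float = 1.0e-3  # proximal aortic wall compliance
    R_aortic_wk_prox: float = 120.0
    C_aortic_wk: float = 0.28e-3
    R_aortic_wk_dist: float = 1300.0
    C_sysven: float = 0.008
    R_sysven: float = 30.0
    R_pulm: float = 120.0
    C_pulm: float = 0.004
    R_pulm_ven: float = 30.0
    C_pa: float = 0.0008
    # initial pressures [dyn/cm^2] used to seed the simulation state
    P_init_art: float = 80.0 * 1333.22
    P_init_ven: float = 12.0 * 1333.22
    P_init_pulm: float = 14.0 * 1333.22
    V_init_lv: float = 120.0
    V_init_la: float = 60.0
    V_init_rv: float = 110.0
    V_init_ra: float = 60.0


def assemble_closed_loop(heart: HeartParams, systemic: SystemicParams,
                         coronary_builder=None) -> Network0D:
    """Build the closed-loop circulation.

    ``coronary_builder(net)`` (optional) appends the coronary/aortic tree
    between the node "aorta" and its own outlet blocks (which must drain
    to "sysven"), and attaches the systemic Windkessel at the aortic
    outlet.  Without a builder, the Windkessel hangs directly off "aorta".
    """
    net = Network0D(period=heart.period)
    h = heart
    net.add_chamber(HeartChamber("LA", h.E_max_la, h.E_min_la, h.V0_la,
                                 h.t_on_atria, h.dur_atria, systemic.V_init_la))
    net.add_chamber(HeartChamber("LV", h.E_max_lv, h.E_min_lv, h.V0_lv,
                                 h.t_on_vent, h.dur_vent, systemic.V_init_lv))
    net.add_chamber(HeartChamber("RA", h.E_max_ra, h.E_min_ra, h.V0_ra,
                                 h.t_on_atria, h.dur_atria, systemic.V_init_ra))
    net.add_chamber(HeartChamber("RV", h.E_max_rv, h.E_min_rv, h.V0_rv,
                                 h.t_on_vent, h.dur_vent, systemic.V_init_rv))
    net.add(Valve("LA", "LV", h.valve_R, h.valve_R_leak, label="mitral"))
    net.add(Valve("LV", "aorta", h.valve_R, h.valve_R_leak, label="aortic"))
    net.add(Valve("RA", "RV", h.valve_R, h.valve_R_leak, label="tricuspid"))
    net.add(Valve("RV", "PA", h.valve_R, h.valve_R_leak, label="pulmonic"))
    net.add(Capacitor("aorta", systemic.C_aorta, label="Cao"))
    # systemic venous return
    net.add(Capacitor("sysven", systemic.C_sysven, label="Cven"))
    net.add(Resistor("sysven", "RA", systemic.R_sysven, label="Rven"))
    # pulmonary circuit
    net.add(Capacitor("PA", systemic.C_pa, label="Cpa"))
    net.add(Resistor("PA", "pulm", systemic.R_pulm, label="Rpulm"))
    net.add(Capacitor("pulm", systemic.C_pulm, label="Cpulm"))
    net.add(Resistor("pulm", "LA", systemic.R_pulm_ven, label="Rpulmven"))
    if coronary_builder is not None:
        coronary_builder(net)
    else:
        attach_windkessel(
            net, "aorta",
            WindkesselBC(systemic.R_aortic_wk_prox, systemic.C_aortic_wk,
                         systemic.R_aortic_wk_dist),
            tag="ao",
        )
    net.meta["heart"] = h
    net.meta["systemic"] = systemic
    return net
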