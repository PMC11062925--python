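import numpy as np
import pytest

from myoperf.network0d import (
    Capacitor,
    FlowSource,
    HeartParams,
    Network0D,
    Resistor,
    SystemicParams,
    assemble_closed_loop,
    attach_outlet_bcs,
    CoronaryOutletBC,
)
from myoperf.lpn_solver import (
    SolverError,
    cardiac_metrics,
    compute_ffr,
    simulate,
    steady_solve,
)


@pytest.fixture(scope="module")
def closed_loop_result():
    net = assemble_closed_loop(HeartParams(), SystemicParams())
    res = simulate(net, n_cycles_max=12, dt=1 / 500, periodicity_tol=1e-3)
    return net, res


class TestSimulate:
    def test_windkessel_matches_analytic(self):
        # constant inflow Q into parallel R-C from rest:
        # P(t) = Q R (1 - exp(-t/(RC)))
        Q, R, C = 5.0, 200.0, 5e-4
        net = Network0D(period=0.4)
        net.fix_pressure("gnd", 0.0)
        net.add(FlowSource("gnd", "n", Q))
        net.add(Resistor("n", "gnd", R))
        net.add(Capacitor("n", C))
        dt = 0.4 / 2000
        res = simulate(net, n_cycles_max=1, dt=dt, periodicity_tol=0.0)
        tau = R * C
        t = res.time
        analytic = Q * R * (1.0 - np.exp(-t / tau))
        num = res.node_pressure("n")
        err = np.max(np.abs(num[1:] - analytic[1:])) / (Q * R)
        assert err < 0.005

    def test_zero_activation_no_flow(self):
        h = HeartParams()
        h.E_max_lv = h.E_min_lv
        h.E_max_la = h.E_min_la
        h.E_max_rv = h.E_min_rv
        h.E_max_ra = h.E_min_ra
        net = assemble_closed_loop(h, SystemicParams())
        res = simulate(net, n_cycles_max=20, dt=1 / 200, periodicity_tol=1e-6)
        pa = res.node_pressure("aorta")
        # pressures settle; aortic flow decays to (near) zero
        assert np.ptp(pa[-50:]) < 1e-3 * 1333.22

    def test_halving_dt_changes_sbp_little(self):
        net1 = assemble_closed_loop(HeartParams(), SystemicParams())
        r1 = simulate(net1, n_cycles_max=10, dt=1 / 1000, periodicity_tol=1e-4)
        net2 = assemble_closed_loop(HeartParams(), SystemicParams())
        r2 = simulate(net2, n_cycles_max=10, dt=1 / 2000, periodicity_tol=1e-4)
        sbp1 = cardiac_metrics(r1).sbp
        sbp2 = cardiac_metrics(r2).sbp
        assert abs(sbp1 - sbp2) < 0.2

    def test_junction_flow_conservation(self, closed_loop_result):
        net, res = closed_loop_result
        # the Newton residual enforces KCL; re-check at the aorta node from
        # the stored waveforms (valve + windkessel + compliance currents)
        c = res.compiled
        dt = res.time[1] - res.time[0]
        i_ao = c.node_index["aorta"]
        # sum of all element flows into "aorta" must equal capacitor storage
        for k in (len(res.time) // 2, len(res.time) - 1):
            total = 0.0
            P = res.P[k]
            Pp = res.P[k - 1]
            for e in c.resistors:
                if e.n1 == "aorta":
                    total -= (P[c.node_index[e.n1]] - P[c.node_index[e.n2]]) / e.R
                elif e.n2 == "aorta":
                    total += (P[c.node_index[e.n1]] - P[c.node_index[e.n2]]) / e.R
            from myoperf.lpn_solver import _valve_flow

            for j, v in enumerate(c.valves):
                dp = P[c.node_index[v.n1]] - P[c.node_index[v.n2]]
                q, _ = _valve_flow(np.array([dp]), np.array([v.R_open]),
                                   np.array([v.R_leak]), np.array([v.w]))
                if v.n1 == "aorta":
                    total -= q[0]
                elif v.n2 == "aorta":
                    total += q[0]
            for j, cap in enumerate(c.caps):
                if cap.node == "aorta":
                    total -= cap.C * (P[i_ao] - Pp[i_ao]) / dt
            assert abs(total) < 1e-5 * 100.0  # mL/s scale


class TestSteady:
    def test_voltage_divider(self):
        net = Network0D()
        net.fix_pressure("src", 90.0)
        net.fix_pressure("gnd", 0.0)
        net.add(Resistor("src", "m", 100.0))
        net.add(Resistor("m", "gnd", 200.0))
        res = steady_solve(net)
        assert res.pressures["m"] == pytest.approx(60.0, rel=1e-12)

    def test_superposition(self):
        def solve(q1, q2):
            net = Network0D()
            net.fix_pressure("gnd", 0.0)
            net.add(Resistor("a", "gnd", 50.0))
            net.add(Resistor("a", "b", 25.0))
            net.add(Resistor("b", "gnd", 75.0))
            net.add(FlowSource("gnd", "a", q1))
            net.add(FlowSource("gnd", "b", q2))
            r = steady_solve(net)
            return np.array([r.pressures["a"], r.pressures["b"]])

        np.testing.assert_allclose(solve(1.0, 2.0), solve(1.0, 0) + solve(0, 2.0),
                                   rtol=1e-12)

    def test_agrees_with_transient_average(self):
        # coronary outlet block with constant inflow: steady == cycle average
        bc = CoronaryOutletBC(R_a=500.0, R_mu=1300.0, R_v=100.0,
                              C_a=1e-6, C_im=1e-6)
        def build():
            net = Network0D(period=1.0)
            net.fix_pressure("sysven", 0.0)
            net.fix_pressure("LV", 50.0 * 1333.22)  # constant P_im reference
            net.add(FlowSource("sysven", "out", 1.2))
            attach_outlet_bcs(net, {0: "out"}, {0: bc})
            return net

        st = steady_solve(build())
        tr = simulate(build(), n_cycles_max=10, dt=1 / 300, periodicity_tol=1e-6)
        p_steady = st.pressures["out"]
        p_mean = tr.mean_pressure("out")
        assert abs(p_mean - p_steady) / p_steady < 0.03

    def test_chambers_rejected(self):
        net = assemble_closed_loop(HeartParams(), SystemicParams())
        with pytest.raises(SolverError):
            steady_solve(net)


class TestCardiacMetrics:
    def test_sbp_dbp_are_extrema(self, closed_loop_result):
        net, res = closed_loop_result
        m = cardiac_metrics(res)
        pa = res.node_pressure("aorta") / 1333.22
        assert m.sbp == pytest.approx(pa.max())
        assert m.dbp == pytest.approx(pa.min())

    def test_ef_identity(self, closed_loop_result):
        net, res = closed_loop_result
        m = cardiac_metrics(res)
        assert m.ejection_fraction * m.edv == pytest.approx(m.stroke_volume,
                                                            rel=1e-12)

    def test_co_equals_mean_aortic_flow(self, closed_loop_result):
        net, res = closed_loop_result
        m = cardiac_metrics(res)
        aortic_valve = [e for e in res.compiled.valves if e.label == "aortic"][0]
        from myoperf.lpn_solver import _valve_flow

        i1 = res.compiled.node_index["LV"]
        i2 = res.compiled.node_index["aorta"]
        dp = res.P[:, i1] - res.P[:, i2]
        q, _ = _valve_flow(dp, np.full_like(dp, aortic_valve.R_open),
                           np.full_like(dp, aortic_valve.R_leak),
                           np.full_like(dp, aortic_valve.w))
        q_mean = np.trapezoid(q, res.time) / (res.time[-1] - res.time[0])
        co_mls = m.cardiac_output * 1000.0 / 60.0
        assert co_mls == pytest.approx(q_mean, rel=0.01)


class TestFFR:
    def test_zero_resistance_path(self):
        net = Network0D()
        net.fix_pressure("aorta", 120000.0)
        net.fix_pressure("gnd", 0.0)
        net.add(Resistor("aorta", "a", 1e-9))
        net.add(Resistor("a", "b", 1e-9))
        net.add(Resistor("b", "gnd", 5000.0))
        res = steady_solve(net)
        prof = compute_ffr(res, ["aorta", "a", "b"])
        np.testing.assert_allclose(prof.ffr, 1.0, atol=1e-9)
        assert not prof.ischemic

    def test_monotone_along_passive_branch(self):
        net = Network0D()
        net.fix_pressure("aorta", 120000.0)
        net.fix_pressure("gnd", 0.0)
        prev = "aorta"
        nodes = ["aorta"]
        for i in range(5):
            n = f"n{i}"
            net.add(Resistor(prev, n, 500.0 * (i + 1)))
            nodes.append(n)
            prev = n
        net.add(Resistor(prev, "gnd", 3000.0))
        res = steady_solve(net)
        prof = compute_ffr(res, nodes)
        assert np.all(np.diff(prof.ffr) <= 1e-12)

    def test_ischemia_flag(self):
        from myoperf.lpn_solver import FFRProfile

        p = FFRProfile(s=np.array([0.0, 1.0]), ffr=np.array([1.0, 0.79]))
        assert p.ischemic
        p2 = FFRProfile(s=np.array([0.0, 1.0]), ffr=np.array([1.0, 0.81]))
        assert not p2.ischemic

    def test_bad_distances(self):
        net = Network0D()
        net.fix_pressure("aorta", 1000.0)
        net.fix_pressure("gnd", 0.0)
        net.add(Resistor("aorta", "a", 10.0))
        net.add(Resistor("a", "gnd", 10.0))
        res = steady_solve(net)
        with pytest.raises(ValueError):
            compute_ffr(res, ["aorta", "a"], distances=[1.0, 0.0])
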