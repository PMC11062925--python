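import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoperf.cco_trees import (
    CCOConfig,
    _GrowingTree,
    allocate_terminals,
    apply_radius_scaling,
    connection_cost,
    grow_tree,
    optimize_bifurcation,
    propagate_scales,
)
from myoperf.core_model import VesselSegment, VesselTree


def chain_tree(n=4, radius=0.2):
    """Single-path tree of n unit segments."""
    segs = [VesselSegment(0, None, [0, 0, 0], [0, 0, -1], radius)]
    for i in range(1, n):
        segs.append(VesselSegment(i, i - 1, [0, 0, -i], [0, 0, -i - 1], radius))
    return VesselTree(segs, 0)


def small_grown_tree(seed=0, n=8):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 2, size=(50, 3))
    return grow_tree(pts, np.array([1.0, 1.0, 3.0]), 0.1, 1.0, n,
                     CCOConfig(seed=seed), territory_volume=8.0, rng=rng)


class TestAllocate:
    def test_even_split(self):
        np.testing.assert_array_equal(allocate_terminals([1.0, 1.0], 10), [5, 5])

    def test_proportional(self):
        np.testing.assert_array_equal(allocate_terminals([3.0, 1.0], 8), [6, 2])

    def test_too_few(self):
        with pytest.raises(ValueError):
            allocate_terminals([1.0, 1.0, 1.0], 2)

    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=20),
           st.integers(20, 700))
    @settings(max_examples=50, deadline=None)
    def test_sum_exact_and_min_one(self, vols, total):
        counts = allocate_terminals(vols, total)
        assert counts.sum() == total
        assert counts.min() >= 1


class TestGrow:
    def test_single_terminal(self):
        pts = np.array([[0.0, 0.0, 1.0]])
        t = grow_tree(pts, np.zeros(3), 0.1, 1.0, 1, CCOConfig(seed=0),
                      territory_volume=1.0)
        assert len(t.segments) == 1
        assert t.outlet_ids == [0]

    def test_binary_tree_counts(self):
        t = small_grown_tree(n=9)
        assert len(t.outlet_ids) == 9
        assert len(t.segments) == 2 * 9 - 1

    def test_symmetric_bifurcation_radius_ratio(self):
        # equal child flows at gamma=3 -> r_child/r_parent = 2^(-1/3)
        t = small_grown_tree(seed=2, n=8)
        for sid, s in t.segments.items():
            ch = t.children(sid)
            if len(ch) == 2:
                n_l = len([o for o in t.subtree_ids(ch[0]) if not t.children(o)])
                n_r = len([o for o in t.subtree_ids(ch[1]) if not t.children(o)])
                if n_l == n_r:
                    r = t.segments[ch[0]].radius / s.radius
                    assert r == pytest.approx(2 ** (-1 / 3), rel=1e-12)

    def test_murray_relation_at_bifurcations(self):
        t = small_grown_tree(seed=3, n=16)
        g = 3.0
        for sid, s in t.segments.items():
            ch = t.children(sid)
            if len(ch) == 2:
                lhs = s.radius**g
                rhs = sum(t.segments[c].radius**g for c in ch)
                assert rhs == pytest.approx(lhs, rel=1e-9)

    @pytest.mark.parametrize("seed", range(50))
    def test_leaf_count_invariant_over_seeds(self, seed):
        t = small_grown_tree(seed=seed, n=5)
        assert len(t.outlet_ids) == 5
        assert len(t.segments) == 9
        # connectivity: every non-leaf has exactly two children
        for sid in t.segments:
            assert len(t.children(sid)) in (0, 2)

    def test_empty_points(self):
        with pytest.raises(ValueError):
            grow_tree(np.empty((0, 3)), np.zeros(3), 0.1, 1.0, 1,
                      CCOConfig(seed=0))


class TestInsertionOptimization:
    def test_optimized_not_worse_than_midpoint(self):
        gt = _GrowingTree(np.zeros(3), np.array([0.0, 0.0, -2.0]), 0.1, 3.0,
                          0.001)
        rng = np.random.default_rng(5)
        for _ in range(10):
            term = rng.uniform(-1, 1, 3) + np.array([0, 0, -1.5])
            x_opt = optimize_bifurcation(gt, 0, term)
            x_mid = 0.5 * (gt.p0[0] + gt.p1[0])
            assert (connection_cost(gt, 0, x_opt, term)
                    <= connection_cost(gt, 0, x_mid, term) + 1e-15)

    def test_total_volume_not_worse_than_naive(self):
        # grow two trees identically except for the bifurcation optimization
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 2, size=(40, 3))
        root = np.array([1.0, 1.0, 3.0])
        cfg = CCOConfig(seed=7)

        def build(optimized: bool):
            r = np.random.default_rng(3)
            gt = _GrowingTree(root, pts[0], 0.1, 3.0, cfg.min_terminal_radius)
            for i in range(1, 8):
                term = pts[i]
                dists = [gt.point_segment_dist(term, s) for s in range(len(gt))]
                seg = int(np.argmin(dists))
                if optimized:
                    x = optimize_bifurcation(gt, seg, term)
                else:
                    x = 0.5 * (gt.p0[seg] + gt.p1[seg])
                gt.insert(seg, x, term)
            return gt.total_volume()

        assert build(True) <= build(False) + 1e-12


class TestRadiusScaling:
    def test_identity(self):
        t = small_grown_tree(seed=1, n=6)
        t2 = apply_radius_scaling(t, {sid: 1.0 for sid in t.outlet_ids})
        for sid in t.segments:
            assert t2.segments[sid].radius == pytest.approx(
                t.segments[sid].radius, rel=1e-14)

    def test_parent_takes_max_of_daughters(self):
        segs = [
            VesselSegment(0, None, [0, 0, 0], [0, 0, -1], 0.3),
            VesselSegment(1, 0, [0, 0, -1], [1, 0, -2], 0.2),
            VesselSegment(2, 0, [0, 0, -1], [-1, 0, -2], 0.2),
        ]
        t = VesselTree(segs, 0)
        plan = propagate_scales(t, {1: 1.2, 2: 0.9})
        assert plan.scales[0] == pytest.approx(1.2)

    def test_child_capped_by_parent(self):
        segs = [
            VesselSegment(0, None, [0, 0, 0], [0, 0, -1], 0.2),
            VesselSegment(1, 0, [0, 0, -1], [1, 0, -2], 0.19),
            VesselSegment(2, 0, [0, 0, -1], [-1, 0, -2], 0.1),
        ]
        t = VesselTree(segs, 0)
        t2 = apply_radius_scaling(t, {1: 1.5, 2: 1.0})
        # daughter 1 requested 0.285 but parent became 0.3 -> allowed
        assert t2.segments[1].radius <= t2.segments[0].radius + 1e-15
        for sid in t2.segments:
            ch = t2.children(sid)
            for c in ch:
                assert t2.segments[c].radius <= t2.segments[sid].radius + 1e-15

    def test_uniform_scale_2_divides_path_resistance_by_16(self):
        from myoperf.core_model import FluidProperties
        from myoperf.network0d import segment_rcl

        t = chain_tree(n=4)
        t2 = apply_radius_scaling(t, {t.outlet_ids[0]: 2.0})
        fluid = FluidProperties()

        def path_r(tree):
            return sum(segment_rcl(s.length, s.radius, fluid)[0]
                       for s in tree.segments.values())

        assert path_r(t2) == pytest.approx(path_r(t) / 16.0, rel=1e-12)

    def test_propagation_idempotent(self):
        t = small_grown_tree(seed=4, n=10)
        scales = {sid: 1.0 + 0.1 * (i % 3) for i, sid in enumerate(t.outlet_ids)}
        plan1 = propagate_scales(t, scales)
        leaf_scales = {sid: plan1.scales[sid] for sid in t.outlet_ids}
        plan2 = propagate_scales(t, leaf_scales)
        assert plan1.scales == plan2.scales

    def test_non_positive_scale_errors(self):
        t = small_grown_tree(seed=1, n=4)
        bad = {sid: 1.0 for sid in t.outlet_ids}
        bad[t.outlet_ids[0]] = -1.0
        with pytest.raises(ValueError):
            apply_radius_scaling(t, bad)

    def test_missing_outlet_errors(self):
        t = small_grown_tree(seed=1, n=4)
        with pytest.raises(ValueError, match="missing"):
            apply_radius_scaling(t, {t.outlet_ids[0]: 1.0})
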