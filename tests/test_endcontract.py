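"""End-contraction paths, the (a, b) optimizer, and the ramp estimator."""

import math

import numpy as np
import pytest

from morphcheck import (
    Morph,
    end_contraction_path,
    estimate_contraction_cost,
    find_intersections,
    make_loop_fixtures,
    omega1_candidate,
    optimize_end_contractions,
    terminal_omega1_price,
)
from morphcheck._geom import point_segment_distance, segment_segment_distance
from morphcheck.endcontract import _downstream_segments


def straight_chain(n=8, spacing=1.0):
    return np.column_stack([np.arange(n) * spacing + 1.0, np.zeros(n),
                            np.zeros(n)])


class TestContractionPath:
    def test_collinear_unobstructed_costs(self):
        pts = straight_chain(7)
        ec = end_contraction_path(pts, 4.0, side="N")
        assert ec.cost == pytest.approx(6.0)  # 3 + 2 + 1 (+ 0 for P4 itself)
        assert ec.m == 4  # m = floor(a) includes the vertex at the target
        assert len(ec.obstruction_points) == 1  # straight shortcuts only

    def test_fractional_target_moves_one_point(self):
        pts = straight_chain(7)
        ec = end_contraction_path(pts, 1.5, side="N")
        assert ec.m == 1
        assert ec.cost == pytest.approx(0.5)

    def test_at_terminus_is_empty(self):
        ec = end_contraction_path(straight_chain(7), 1.0, side="N")
        assert ec.m == 0 and ec.cost == 0.0

    def test_c_side_mirrors(self):
        pts = straight_chain(7)
        n_side = end_contraction_path(pts, 4.0, side="N")
        c_side = end_contraction_path(pts[::-1], 4.0, side="N")
        mirrored = end_contraction_path(pts, 4.0, side="C")
        assert mirrored.cost == pytest.approx(c_side.cost)
        assert mirrored.cost == pytest.approx(n_side.cost)  # symmetric chain

    def _blocked_chain(self):
        """N-tail hooked around a downstream strand: the straight shortcut
        from P1 to the target crosses the blocking strand."""
        pts = np.array([
            [-6.0, 8.0, 0.0],   # P1: pulled back over the blocker
            [2.0, 8.0, 0.0],    # P2
            [6.0, 4.0, 0.0],    # P3
            [4.0, 0.0, 0.0],    # P4 = contraction target region
            [0.0, 0.1, 4.0],    # downstream strand crossing above the tail
            [0.0, 0.1, -6.0],
            [-8.0, 0.0, -6.0],
            [-14.0, 0.0, -6.0],
        ])
        return pts

    def test_blocked_path_detours_and_clears(self):
        pts = self._blocked_chain()
        a = 4.0
        ec = end_contraction_path(pts, a, side="N")
        straight = sum(
            np.linalg.norm(pts[r - 1] - pts[3]) for r in range(1, 4)
        )
        assert len(ec.obstruction_points) >= 2  # at least one detour point
        assert ec.cost > straight
        # clearance of the full obstruction chain against downstream segments
        # (the first leg and the partial downstream segment share the target
        # point by construction, so that one touching pair is exempt)
        segs = _downstream_segments(pts, a)
        chain = ec.obstruction_points
        for i in range(len(chain) - 1):
            for (p, q) in segs:
                if i == 0 and np.allclose(p, chain[0]):
                    continue
                assert segment_segment_distance(chain[i], chain[i + 1], p, q) \
                    > 1e-6

    def test_cost_bounded_below_by_straight_lines(self, rng):
        for _ in range(20):
            steps = rng.normal(size=(11, 3)) * 3
            pts = np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)])
            a = float(rng.uniform(2.5, 8.5))
            ec = end_contraction_path(pts, a, side="N")
            from morphcheck.reparam import eval_curve

            target = eval_curve(pts, a)
            lower = sum(
                np.linalg.norm(pts[r - 1] - target)
                for r in range(1, math.floor(a) + 1)
            )
            assert ec.cost >= lower - 1e-9


class TestEstimate:
    @pytest.mark.parametrize("k,expected", [(0, 0.0), (17, 225.0), (20, 300.0)])
    def test_ramp_closed_form(self, k, expected):
        assert estimate_contraction_cost(k) == pytest.approx(expected)

    def test_monotone(self):
        vals = [estimate_contraction_cost(k) for k in range(40)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestOptimizer:
    def test_no_essentials_no_contraction(self, crossing_pair):
        c0, c1 = crossing_pair
        m = Morph(curve0=c0.points, curve1=c1.points)
        a, b, cost, objs = optimize_end_contractions([], m)
        assert cost == 0.0 and a == 1.0 and b == float(m.m)

    def test_n_proximal_essential_contracts_n_side(self, rng):
        """One essential near the N-terminus: contracting the short N-tail
        beats contracting the (extended) stretch after b."""
        c0, c1 = make_loop_fixtures("removable_loop")
        # lengthen the C-tail identically in both structures so the N side
        # is strictly cheaper
        last = c0.points[-1]
        step = c0.points[-1] - c0.points[-2]
        extra = np.array([last + (k + 1) * step for k in range(5)])
        p0 = np.vstack([c0.points, extra])
        p1 = np.vstack([c1.points, extra])
        m = Morph(curve0=p0, curve1=p1)
        si = find_intersections(m)[0]
        a, b, cost, _ = optimize_end_contractions([si], m)
        assert a == pytest.approx(si.a)
        assert b == float(m.m)
        assert cost > 0

    def test_candidates_match_dense_grid(self, rng):
        """The n+1 candidate pairs achieve the dense-grid optimum."""
        steps = rng.normal(size=(15, 3)) * 3
        pts0 = np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)])
        pts1 = pts0 + rng.normal(scale=2.0, size=pts0.shape)
        m = Morph(curve0=pts0, curve1=pts1)
        ints = find_intersections(m)
        if len(ints) < 2:  # enrich deterministically if the draw is sparse
            ints = ints + [
                type(i)(a=4.3, b=9.7, sign=1, t_star=0.5) for i in ints[:1]
            ]
        ess = sorted(ints, key=lambda s: s.a)[:3]
        a_opt, b_opt, cost_opt, _ = optimize_end_contractions(
            ess, m, use_estimates=True
        )
        L = float(m.m)
        from morphcheck.endcontract import (_c_contraction_cost,
                                            _n_contraction_cost)

        grid_best = np.inf
        for a in np.arange(1.0, L, 0.25):
            for b in np.arange(a + 0.25, L + 1e-9, 0.25):
                if not all(s.a <= a or b <= s.b for s in ess):
                    continue
                cn, _ = _n_contraction_cost(m, a, True)
                cc, _ = _c_contraction_cost(m, b, True)
                grid_best = min(grid_best, cn + cc)
        assert cost_opt <= grid_best + 1e-9

    def test_limit_can_forbid_all_candidates(self, crossing_pair):
        c0, c1 = crossing_pair
        m = Morph(curve0=c0.points, curve1=c1.points)
        si = find_intersections(m)[0]
        assert optimize_end_contractions([si], m, limit=2.0) is None


class TestTerminalOmega1:
    def _setup(self):
        c0, c1 = make_loop_fixtures("removable_loop")
        m = Morph(curve0=c0.points, curve1=c1.points)
        si = find_intersections(m)[0]
        return m, si

    def test_cheap_contraction_wins(self):
        m, si = self._setup()
        cand = omega1_candidate(si, m, max_length=50.0)
        assert cand.feasible
        priced = terminal_omega1_price(si, m, cand, max_length=50.0,
                                       use_estimates=True)
        from morphcheck.endcontract import _n_contraction_cost

        contraction, _ = _n_contraction_cost(m, si.a, True)
        assert priced.price == pytest.approx(min(cand.price, contraction))

    def test_mid_chain_unchanged(self, crossing_pair):
        c0, c1 = crossing_pair
        m = Morph(curve0=c0.points, curve1=c1.points)
        si = find_intersections(m)[0]
        cand = omega1_candidate(si, m, max_length=25.0)
        out = terminal_omega1_price(si, m, cand, max_length=10.0)
        assert out is cand  # far from both termini: untouched

    def test_infeasible_omega1_rescued_by_contraction(self):
        c0, c1 = make_loop_fixtures("threaded_loop")
        m = Morph(curve0=c0.points, curve1=c1.points)
        si = find_intersections(m)[0]
        cand = omega1_candidate(si, m, max_length=50.0)
        assert not cand.feasible
        priced = terminal_omega1_price(si, m, cand, max_length=50.0,
                                       use_estimates=True)
        assert priced.feasible and priced.price > 0
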