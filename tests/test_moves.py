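"""Disk freeness, Ω1/Ω2 removability decisions and move prices."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from morphcheck import (
    Morph,
    disk_is_free,
    find_intersections,
    omega1_candidate,
    omega2_candidate,
)
from morphcheck._geom import point_line_distance
from morphcheck.moves import Disk, build_loop_disk
from oracles import brute_disk_is_free


def _circle_disk(radius=4.0, n=12, center=(0.0, 0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    boundary = np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th),
         np.full(n, center[2])]
    )
    return Disk(boundary=boundary, centroid=boundary.mean(axis=0))


class TestDiskIsFree:
    def test_remote_tail_is_free(self):
        disk = _circle_disk()
        tail = np.column_stack([np.arange(6.0) * 3.8 + 60.0, np.zeros(6),
                                np.zeros(6)])
        free, blocker = disk_is_free(disk, tail, excluded=[])
        assert free and blocker is None

    def test_threading_segment_detected(self):
        disk = _circle_disk()
        curve = np.array([[0, 0, -6.0], [0, 0, 6.0], [10, 0, 6.0]])
        free, blocker = disk_is_free(disk, curve, excluded=[])
        assert not free
        assert blocker == 0

    def test_matches_brute_force_on_random_instances(self, rng):
        agree = 0
        for _ in range(500):
            n = int(rng.integers(6, 14))
            th = np.sort(rng.uniform(0, 2 * np.pi, size=n))
            r = rng.uniform(2.0, 6.0)
            boundary = np.column_stack(
                [r * np.cos(th), r * np.sin(th),
                 rng.normal(scale=0.3, size=n)]
            )
            disk = Disk(boundary=boundary, centroid=boundary.mean(axis=0))
            steps = rng.normal(size=(int(rng.integers(4, 10)), 3)) * 3
            curve = rng.uniform(-8, 8, size=3) + np.vstack(
                [np.zeros(3), np.cumsum(steps, axis=0)]
            )
            ours, _ = disk_is_free(disk, curve, excluded=[])
            oracle = brute_disk_is_free(disk, curve, excluded=[])
            assert ours == oracle
            agree += 1
        assert agree == 500


class TestOmega1:
    def test_max_length_gate_short_circuits(self, loop_pairs):
        c0, c1 = loop_pairs["removable_loop"]
        m = Morph(curve0=c0.points, curve1=c1.points)
        si = find_intersections(m)[0]
        cand = omega1_candidate(si, m, max_length=2.0)
        assert not cand.feasible
        assert cand.blocking == "max_length"
        assert cand.backbone_length == pytest.approx(si.b - si.a)

    def test_removable_loop_feasible_price_formula(self, loop_pairs):
        c0, c1 = loop_pairs["removable_loop"]
        m = Morph(curve0=c0.points, curve1=c1.points)
        si = find_intersections(m)[0]
        cand = omega1_candidate(si, m, max_length=50.0)
        assert cand.feasible
        slice_curve = m.slice_at(si.t_star)
        disk = build_loop_disk(slice_curve, si.a, si.b)
        from morphcheck.reparam import eval_curve

        x = eval_curve(slice_curve, si.a)
        expected = 2.0 * sum(
            point_line_distance(p, x, disk.centroid) for p in disk.boundary
        )
        assert cand.price == pytest.approx(expected, rel=1e-12)
        assert cand.writhe_jump == 2 * si.sign

    def test_threaded_loop_infeasible_with_blocker(self, loop_pairs):
        c0, c1 = loop_pairs["threaded_loop"]
        m = Morph(curve0=c0.points, curve1=c1.points)
        si = find_intersections(m)[0]
        cand = omega1_candidate(si, m, max_length=50.0)
        assert not cand.feasible
        assert cand.blocking.startswith("segment")


class TestOmega2:
    def test_slide_pair_feasible_with_price(self, loop_pairs):
        c0, c1 = loop_pairs["slide_pair"]
        m = Morph(curve0=c0.points, curve1=c1.points)
        s1, s2 = find_intersections(m)
        assert s1.sign + s2.sign == 0
        cand = omega2_candidate(s1, s2, m, max_length=20.0)
        assert cand.feasible
        t_avg = 0.5 * (s1.t_star + s2.t_star)
        slice_curve = m.slice_at(t_avg)
        lo, hi = sorted([s1.a, s2.a])
        disk = build_loop_disk(
            slice_curve, lo, hi,
            extra_arc=(min(s1.b, s2.b), max(s1.b, s2.b)),
        )
        from morphcheck.reparam import eval_curve

        x1, x2 = eval_curve(slice_curve, lo), eval_curve(slice_curve, hi)
        expected = 2.0 * sum(
            point_line_distance(p, x1, x2) for p in disk.boundary
        )
        assert cand.price == pytest.approx(expected, rel=1e-12)

    def test_length_gate(self, loop_pairs):
        c0, c1 = loop_pairs["slide_pair"]
        m = Morph(curve0=c0.points, curve1=c1.points)
        s1, s2 = find_intersections(m)
        cand = omega2_candidate(s1, s2, m, max_length=5.0)
        assert not cand.feasible and cand.blocking == "max_length"

    def test_same_sign_pair_rejected(self, loop_pairs):
        c0, c1 = loop_pairs["slide_pair"]
        m = Morph(curve0=c0.points, curve1=c1.points)
        s1, s2 = find_intersections(m)
        s2_flipped = type(s2)(a=s2.a, b=s2.b, sign=s1.sign, t_star=s2.t_star,
                              seg_i=s2.seg_i, seg_j=s2.seg_j, k=s2.k)
        cand = omega2_candidate(s1, s2_flipped, m, max_length=20.0)
        assert not cand.feasible and cand.blocking == "same_sign"

    def test_threaded_disk_blocks_pair(self, loop_pairs):
        """A strand through the spanned disk makes the slide infeasible."""
        c0, c1 = loop_pairs["slide_pair"]
        # a static strand slotted between the S strand (z = 0) and the V
        # bottom (z = -2): it pierces the spanned disk without ever crossing
        # the moving curve
        thread = np.array([[0.0, 6.0, -1.0], [0.0, -6.0, -1.0]])
        p0 = np.vstack([c0.points, thread])
        p1 = np.vstack([c1.points, thread])
        m = Morph(curve0=p0, curve1=p1)
        ints = find_intersections(m)
        pair = [s for s in ints if s.b <= len(c0.points) + 1]
        assert len(pair) == 2
        cand = omega2_candidate(pair[0], pair[1], m, max_length=20.0)
        assert not cand.feasible


class TestMoveProperties:
    def _crossing_morph(self, crossing_pair, transform=None):
        c0, c1 = crossing_pair
        p0, p1 = c0.points, c1.points
        if transform is not None:
            p0, p1 = transform(p0), transform(p1)
        return Morph(curve0=p0, curve1=p1)

    def test_price_rigid_invariance_and_scaling(self, crossing_pair):
        m = self._crossing_morph(crossing_pair)
        si = find_intersections(m)[0]
        base = omega1_candidate(si, m, max_length=25.0)
        assert base.feasible

        R = Rotation.random(random_state=3).as_matrix()
        shift = np.array([5.0, -11.0, 2.0])
        m_rot = self._crossing_morph(crossing_pair,
                                     transform=lambda p: p @ R.T + shift)
        si_rot = find_intersections(m_rot)[0]
        rot = omega1_candidate(si_rot, m_rot, max_length=25.0)
        assert rot.price == pytest.approx(base.price, rel=1e-6)

        m_scaled = self._crossing_morph(crossing_pair,
                                        transform=lambda p: 2.0 * p)
        si_s = find_intersections(m_scaled)[0]
        scaled = omega1_candidate(si_s, m_scaled, max_length=25.0)
        assert scaled.price == pytest.approx(2.0 * base.price, rel=1e-6)

    def test_feasibility_monotone_in_max_length(self, crossing_pair,
                                                loop_pairs):
        cases = [self._crossing_morph(crossing_pair)]
        for kind in ("removable_loop", "threaded_loop"):
            c0, c1 = loop_pairs[kind]
            cases.append(Morph(curve0=c0.points, curve1=c1.points))
        for m in cases:
            for si in find_intersections(m):
                prev = False
                for L in (0.0, 5.0, 10.0, 20.0, 40.0):
                    feas = omega1_candidate(si, m, L).feasible
                    assert feas or not prev  # once feasible, stays feasible
                    prev = prev or feas

    def test_omega2_pair_sign_sum_zero(self, loop_pairs):
        c0, c1 = loop_pairs["slide_pair"]
        m = Morph(curve0=c0.points, curve1=c1.points)
        s1, s2 = find_intersections(m)
        cand = omega2_candidate(s1, s2, m, max_length=20.0)
        assert cand.feasible
        assert s1.sign + s2.sign == 0
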