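"""Local removability of self-intersections by 3D Reidemeister-style moves.

An intersection (a, b, sign, t*) is Ω1-removable if the topological disk
spanned by the loop P_a(t*)...P_b(t*) (triangle fan to the loop's center of
mass) is disjoint from the rest of the t*-slice curve and the loop is short
enough (b - a <= MaxLength).  Its price P1 is twice the sum of distances from
the loop points to the line through the self-intersection point and the loop
centroid — the axis around which the loop can be rotated to the other side.

A pair of opposite-sign intersections is Ω2-removable if the disk spanned at
the average time by the two arcs connecting the intersection points is free,
the tracks swept by the two intersection points over [t*_j, t*_k] stay clear
of the rest of the moving curve, and the combined backbone length is within
MaxLength.  Its price P2 is twice the sum of distances from the loop points
to the line connecting the two intersection points at the average time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._geom import (
    point_line_distance,
    segment_segment_distance,
    segment_triangle_intersect,
)
from .intersect import SelfIntersection
from .morphgeo import Morph
from .reparam import eval_curve

__all__ = [
    "Disk",
    "MoveCandidate",
    "build_loop_disk",
    "disk_is_free",
    "omega1_candidate",
    "omega2_candidate",
]

TRACK_SAMPLES = 64
TRACK_CLEARANCE = 1e-6  # Å


@dataclass
class Disk:
    """Triangle fan over a closed loop: consecutive boundary pairs + centroid."""

    boundary: np.ndarray  # (k, 3), closed implicitly (last connects to first)
    centroid: np.ndarray

    def triangles(self):
        k = len(self.boundary)
        for idx in range(k):
            yield self.boundary[idx], self.boundary[(idx + 1) % k], self.centroid


@dataclass
class MoveCandidate:
    kind: str  # "omega1" | "omega2"
    members: List[int]  # intersection indices k
    backbone_length: float
    price: float
    feasible: bool
    blocking: Optional[str] = None
    writhe_jump: int = 0  # +-2 for omega1 moves; 0 for omega2


def _arc_points(curve: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Sample the t-slice polyline at params lo, interior vertices, hi."""
    params = [lo]
    start = math.ceil(lo)
    if abs(start - lo) < 1e-9:
        start += 1
    stop = math.floor(hi)
    if abs(stop - hi) < 1e-9:
        stop -= 1
    params.extend(range(start, stop + 1))
    params.append(hi)
    return eval_curve(curve, np.array(params, dtype=float))


def build_loop_disk(curve: np.ndarray, lo: float, hi: float,
                    extra_arc: Optional[Tuple[float, float]] = None) -> Disk:
    """Disk over the loop from param lo to hi on a t-slice curve.

    With ``extra_arc`` (for Ω2) the boundary is the lo-hi arc followed by the
    second arc traversed backwards, closing the two-strand loop.
    """
    pts = _arc_points(curve, lo, hi)
    if extra_arc is not None:
        b_lo, b_hi = extra_arc
        pts2 = _arc_points(curve, b_lo, b_hi)
        pts = np.vstack([pts, pts2[::-1]])
    centroid = pts.mean(axis=0)
    return Disk(boundary=pts, centroid=centroid)


def _tested_segments(m: int, excluded: Sequence[Tuple[float, float]]):
    """0-based segment indices whose full span lies outside every excluded
    open parameter range (a, b); segment l spans params [l+1, l+2]."""
    out = []
    for seg in range(m - 1):
        lo_p, hi_p = seg + 1, seg + 2
        ok = True
        for (a, b) in excluded:
            if not (hi_p <= math.floor(a) or lo_p >= math.ceil(b)):
                ok = False
                break
        if ok:
            out.append(seg)
    return out


def disk_is_free(
    disk: Disk,
    curve: np.ndarray,
    excluded: Sequence[Tuple[float, float]],
) -> Tuple[bool, Optional[int]]:
    """True iff no curve segment outside the excluded ranges intersects any
    fan triangle.

    Segments are sorted by the distance from the disk centroid to their
    midpoints; the scan stops early once the triangle-inequality bound
    (max boundary radius + half segment length < midpoint distance) excludes
    all remaining segments.  Returns (free, first blocking segment index).
    """
    curve = np.asarray(curve, dtype=float)
    m = len(curve)
    segs = _tested_segments(m, excluded)
    if not segs:
        return True, None
    c = disk.centroid
    radius = float(np.max(np.linalg.norm(disk.boundary - c, axis=1)))
    p = curve[segs]
    q = curve[[s + 1 for s in segs]]
    mids = 0.5 * (p + q)
    rho = np.linalg.norm(mids - c, axis=1)
    half = 0.5 * np.linalg.norm(q - p, axis=1)
    order = np.argsort(rho)
    # suffix max of half-lengths in sorted order for a sound early stop
    half_sorted = half[order]
    suffix_max = np.maximum.accumulate(half_sorted[::-1])[::-1]
    tris = [t for t in disk.triangles()]
    for rank, oi in enumerate(order):
        if rho[order[rank]] - suffix_max[rank] > radius:
            break
        a, b = p[oi], q[oi]
        for (t0, t1, t2) in tris:
            if segment_triangle_intersect(a, b, t0, t1, t2):
                return False, segs[oi]
    return True, None


def omega1_candidate(
    si: SelfIntersection, morph: Morph, max_length: float
) -> MoveCandidate:
    """Ω1 removability and price for a single intersection."""
    length = si.b - si.a
    if length > max_length:
        return MoveCandidate(
            kind="omega1",
            members=[si.k],
            backbone_length=length,
            price=0.0,
            feasible=False,
            blocking="max_length",
            writhe_jump=2 * si.sign,
        )
    slice_curve = morph.slice_at(si.t_star)
    disk = build_loop_disk(slice_curve, si.a, si.b)
    free, blocker = disk_is_free(disk, slice_curve, [(si.a, si.b)])
    if not free:
        return MoveCandidate(
            kind="omega1",
            members=[si.k],
            backbone_length=length,
            price=0.0,
            feasible=False,
            blocking=f"segment {blocker}",
            writhe_jump=2 * si.sign,
        )
    x = eval_curve(slice_curve, si.a)  # the self-intersection point
    price = 2.0 * sum(
        point_line_distance(pt, x, disk.centroid) for pt in disk.boundary
    )
    return MoveCandidate(
        kind="omega1",
        members=[si.k],
        backbone_length=length,
        price=float(price),
        feasible=True,
        writhe_jump=2 * si.sign,
    )


def _track_point(morph: Morph, t: float, seg_i: int, seg_j: int) -> np.ndarray:
    """Near-intersection point of segments seg_i, seg_j at time t: the
    midpoint of their closest-point pair (equals the intersection at t*)."""
    p = morph.slice_at(t)
    p0, p1 = p[seg_i], p[seg_i + 1]
    q0, q1 = p[seg_j], p[seg_j + 1]
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    b = float(d1 @ d2)
    c = float(d1 @ r)
    f = float(d2 @ r)
    den = a * e - b * b
    if den > 1e-14:
        s = np.clip((b * f - c * e) / den, 0.0, 1.0)
    else:
        s = 0.0
    t2 = np.clip((b * s + f) / e, 0.0, 1.0) if e > 1e-14 else 0.0
    c1 = p0 + s * d1
    c2 = q0 + t2 * d2
    return 0.5 * (c1 + c2)


def _tracks_clear(
    morph: Morph,
    first: SelfIntersection,
    second: SelfIntersection,
    excluded: Sequence[Tuple[float, float]],
) -> Tuple[bool, Optional[str]]:
    """Check the two intersection-point tracks over [t*_j, t*_k] against the
    remainder of the moving curve at matching times."""
    t_lo, t_hi = first.t_star, second.t_star
    if t_hi - t_lo < 1e-12:
        return True, None
    ts = np.linspace(t_lo, t_hi, TRACK_SAMPLES)
    for si in (first, second):
        track = np.array([_track_point(morph, t, si.seg_i, si.seg_j) for t in ts])
        for k in range(len(ts) - 1):
            tm = 0.5 * (ts[k] + ts[k + 1])
            p = morph.slice_at(tm)
            for seg in _tested_segments(morph.m, excluded):
                d = segment_segment_distance(
                    track[k], track[k + 1], p[seg], p[seg + 1]
                )
                if d <= TRACK_CLEARANCE:
                    return False, f"track of {si.k} blocked by segment {seg}"
    return True, None


def omega2_candidate(
    si_j: SelfIntersection,
    si_k: SelfIntersection,
    morph: Morph,
    max_length: float,
) -> MoveCandidate:
    """Ω2 removability and price for a pair of opposite-sign intersections."""
    first, second = (si_j, si_k) if si_j.t_star <= si_k.t_star else (si_k, si_j)
    length = (si_j.b - si_j.a) + (si_k.b - si_k.a)
    members = [si_j.k, si_k.k]
    if si_j.sign + si_k.sign != 0:
        return MoveCandidate(
            kind="omega2", members=members, backbone_length=length,
            price=0.0, feasible=False, blocking="same_sign",
        )
    if length > max_length:
        return MoveCandidate(
            kind="omega2", members=members, backbone_length=length,
            price=0.0, feasible=False, blocking="max_length",
        )
    p_lo, p_hi = (si_j, si_k) if si_j.a <= si_k.a else (si_k, si_j)
    a_arc = (p_lo.a, p_hi.a)
    b_arc = (min(p_lo.b, p_hi.b), max(p_lo.b, p_hi.b))
    if a_arc[1] > b_arc[0]:
        return MoveCandidate(
            kind="omega2", members=members, backbone_length=length,
            price=0.0, feasible=False, blocking="interleaved_arcs",
        )
    t_avg = 0.5 * (si_j.t_star + si_k.t_star)
    slice_curve = morph.slice_at(t_avg)
    disk = build_loop_disk(slice_curve, *a_arc, extra_arc=b_arc)
    free, blocker = disk_is_free(disk, slice_curve, [a_arc, b_arc])
    if not free:
        return MoveCandidate(
            kind="omega2", members=members, backbone_length=length,
            price=0.0, feasible=False, blocking=f"segment {blocker}",
        )
    clear, why = _tracks_clear(morph, first, second, [a_arc, b_arc])
    if not clear:
        return MoveCandidate(
            kind="omega2", members=members, backbone_length=length,
            price=0.0, feasible=False, blocking=why,
        )
    x1 = eval_curve(slice_curve, a_arc[0])
    x2 = eval_curve(slice_curve, a_arc[1])
    price = 2.0 * sum(point_line_distance(pt, x1, x2) for pt in disk.boundary)
    return MoveCandidate(
        kind="omega2", members=members, backbone_length=length,
        price=float(price), feasible=True,
    )
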