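"""Terminus contractions that avoid essential self-intersections.

A self-intersection (a, b, sign, t*) that cannot be removed locally may be
avoided by pulling a terminus free: an N-contraction moves every point
upstream of P_a to P_a before the morph (and reverses the contraction after),
so the morph restricted to [a, L] never sees the upstream strand.  The
contraction path is shortened greedily: each upstream point takes the straight
shortcut to the current obstruction point when the connecting triangle is
disjoint from the curve downstream of a; otherwise a new obstruction point
inside the triangle is chosen to minimize the two-leg path while avoiding all
downstream segments.

The cost of the move is the distance traveled in both end structures plus
m = floor(a) times the displacement of P_a under the original morph (all m
contracted points ride along).  Restricted to the backbone the cost would be
quadratic in the distance to the terminus; the greedy path is far shorter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._geom import segment_segment_distance, segment_triangle_intersect
from .intersect import SelfIntersection
from .morphgeo import Morph
from .moves import MoveCandidate
from .reparam import eval_curve

__all__ = [
    "EndContraction",
    "end_contraction_path",
    "optimize_end_contractions",
    "estimate_contraction_cost",
    "terminal_omega1_price",
]

PATH_CLEARANCE = 1e-6  # Å, required distance of contraction paths to the curve
BARY_GRID = 15  # barycentric candidate grid per triangle
RAMP_LENGTH = 17  # residues over which contraction travel grows linearly
RAMP_PLATEAU = 25.0  # Å, saturated per-residue travel distance


@dataclass
class EndContraction:
    """One-structure contraction of a chain end to the point at parameter a."""

    side: str  # "N" or "C"
    target_param: float
    m: int  # number of contracted points
    obstruction_points: np.ndarray  # chain from the target outward, (k, 3)
    per_point_travel: List[float]
    cost: float  # total distance traveled in this structure


def _downstream_segments(points: np.ndarray, a: float):
    """Segments of the curve at parameters >= a (including the partial one)."""
    n = len(points)
    target = eval_curve(points, a)
    start = math.ceil(a)
    segs = []
    if start <= n and abs(start - a) > 1e-9:
        segs.append((target, points[start - 1]))
    for v in range(start, n):
        segs.append((points[v - 1], points[v]))
    return segs


def _triangle_free(tri, segments) -> Tuple[bool, List[np.ndarray]]:
    """Whether any downstream segment pierces the triangle; returns the
    piercing points for obstruction-candidate construction."""
    t0, t1, t2 = tri
    hits = []
    for (p, q) in segments:
        if segment_triangle_intersect(p, q, t0, t1, t2):
            # locate the plane crossing for the offset candidate
            n = np.cross(t1 - t0, t2 - t0)
            nn = np.linalg.norm(n)
            if nn > 1e-12:
                n = n / nn
                dp = float(n @ (p - t0))
                dq = float(n @ (q - t0))
                if abs(dp - dq) > 1e-14:
                    s = np.clip(dp / (dp - dq), 0.0, 1.0)
                    hits.append(p + s * (q - p))
    return len(hits) == 0, hits


def _legs_clear(head, cand, pr, segments) -> bool:
    for (p, q) in segments:
        if segment_segment_distance(head, cand, p, q) <= PATH_CLEARANCE:
            return False
        if segment_segment_distance(cand, pr, p, q) <= PATH_CLEARANCE:
            return False
    return True


def _best_obstruction_point(head, p_next, p_r, hits, segments):
    """Candidate inside triangle (head, p_next, p_r) minimizing the two-leg
    path head -> cand -> p_r while clearing all downstream segments."""
    cands = []
    g = BARY_GRID
    for iu in range(g + 1):
        for iv in range(g + 1 - iu):
            u = iu / g
            v = iv / g
            w = 1.0 - u - v
            cands.append(u * head + v * p_next + w * p_r)
    for h in hits:
        d = head - h
        L = np.linalg.norm(d)
        if L > 1e-9:
            cands.append(h + 0.5 * d / L)
    best = None
    for cand in cands:
        length = float(np.linalg.norm(head - cand) + np.linalg.norm(cand - p_r))
        if best is not None and length >= best[0]:
            continue
        if _legs_clear(head, cand, p_r, segments):
            best = (length, cand)
    return None if best is None else best[1]


def end_contraction_path(points, a: float, side: str = "N") -> EndContraction:
    """Greedy shortest contraction of one chain end (one structure, t fixed).

    ``points`` is the (n, 3) t-slice; for side="N" the points at parameters
    1..floor(a) contract to P_a; side="C" mirrors (parameters ceil(a)..n).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(pts)
    if side == "C":
        inner = end_contraction_path(pts[::-1], n + 1 - a, side="N")
        return EndContraction(
            side="C",
            target_param=a,
            m=inner.m,
            obstruction_points=inner.obstruction_points,
            per_point_travel=inner.per_point_travel,
            cost=inner.cost,
        )
    if a <= 1.0 + 1e-12:
        return EndContraction(
            side="N", target_param=a, m=0,
            obstruction_points=np.asarray([eval_curve(pts, max(a, 1.0))]),
            per_point_travel=[], cost=0.0,
        )
    if a > n:
        raise ValueError("contraction parameter outside the chain")
    m = math.floor(a)
    target = eval_curve(pts, a)
    segments = _downstream_segments(pts, a)
    chain = [target]
    legsum = 0.0
    travels: List[float] = []
    total = 0.0
    for r in range(m, 0, -1):
        head = chain[-1]
        p_r = pts[r - 1]
        if r == m:
            # P_m slides along its own (partial) segment to P_a: always free
            travel = float(np.linalg.norm(p_r - head)) + legsum
        else:
            p_next = pts[r]  # P_{r+1}
            free, hits = _triangle_free((head, p_next, p_r), segments)
            if free:
                travel = float(np.linalg.norm(p_r - head)) + legsum
            else:
                cand = _best_obstruction_point(head, p_next, p_r, hits, segments)
                if cand is None:
                    cand = p_next  # fall back to routing along the backbone
                legsum += float(np.linalg.norm(head - cand))
                chain.append(cand)
                head = cand
                travel = float(np.linalg.norm(p_r - head)) + legsum
        travels.append(travel)
        total += travel
    return EndContraction(
        side="N",
        target_param=a,
        m=m,
        obstruction_points=np.asarray(chain),
        per_point_travel=travels,
        cost=total,
    )


def estimate_contraction_cost(k: int) -> float:
    """Estimated one-structure travel for contracting k residues:
    per-residue distance ramps linearly to 25 Å over 17 residues, then
    plateaus at 25 Å."""
    if k < 0:
        raise ValueError("k must be >= 0")
    total = 0.0
    for r in range(1, k + 1):
        total += min(RAMP_PLATEAU * r / RAMP_LENGTH, RAMP_PLATEAU)
    return total


def _n_contraction_cost(morph: Morph, a: float, use_estimates: bool):
    """Both-structure cost of an N-contraction to parameter a."""
    if a <= 1.0 + 1e-12:
        return 0.0, []
    m = math.floor(a)
    disp = float(
        np.linalg.norm(eval_curve(morph.curve1, a) - eval_curve(morph.curve0, a))
    )
    if use_estimates:
        return 2.0 * estimate_contraction_cost(m) + m * disp, []
    c0 = end_contraction_path(morph.curve0, a, side="N")
    c1 = end_contraction_path(morph.curve1, a, side="N")
    return c0.cost + c1.cost + m * disp, [c0, c1]


def _c_contraction_cost(morph: Morph, b: float, use_estimates: bool):
    L = morph.m
    if b >= L - 1e-12:
        return 0.0, []
    count = L - math.ceil(b) + 1
    disp = float(
        np.linalg.norm(eval_curve(morph.curve1, b) - eval_curve(morph.curve0, b))
    )
    if use_estimates:
        return 2.0 * estimate_contraction_cost(count) + count * disp, []
    c0 = end_contraction_path(morph.curve0, b, side="C")
    c1 = end_contraction_path(morph.curve1, b, side="C")
    return c0.cost + c1.cost + count * disp, [c0, c1]


def optimize_end_contractions(
    essentials: Sequence[SelfIntersection],
    morph: Morph,
    limit: Optional[float] = None,
    use_estimates: bool = False,
):
    """Cheapest combined N/C contraction removing every essential intersection.

    Minimizes NContraction(a) + CContraction(b) over 1 <= a < b <= L subject
    to a_i <= a or b <= b_i for every essential i.  Only the n+1 candidate
    pairs a = a_j, b = min(b_{j+1}, ..., b_n, L) (j = 0..n, with a_0 = 1)
    can be optimal, so only those are evaluated.  ``limit`` bounds the number
    of residues either contraction may involve.

    Returns (a, b, total_cost, contraction objects) or None if no candidate
    is admissible under ``limit``.
    """
    L = float(morph.m)
    if not essentials:
        return (1.0, L, 0.0, [])
    ess = sorted(essentials, key=lambda s: s.a)
    n = len(ess)
    best = None
    for j in range(n + 1):
        a = 1.0 if j == 0 else ess[j - 1].a
        remaining_b = [s.b for s in ess[j:]]
        b = min(remaining_b + [L])
        if not (a < b):
            continue
        if limit is not None:
            n_count = 0 if a <= 1 else math.floor(a)
            c_count = 0 if b >= L else L - math.ceil(b) + 1
            if n_count > limit or c_count > limit:
                continue
        cost_n, objs_n = _n_contraction_cost(morph, a, use_estimates)
        cost_c, objs_c = _c_contraction_cost(morph, b, use_estimates)
        total = cost_n + cost_c
        if best is None or total < best[2]:
            best = (a, b, total, objs_n + objs_c)
    return best


def terminal_omega1_price(
    si: SelfIntersection,
    morph: Morph,
    omega1: MoveCandidate,
    max_length: float,
    window: Optional[float] = None,
    use_estimates: bool = False,
) -> MoveCandidate:
    """Treat an end-proximal intersection as Ω1-removable at the cheaper of
    its Ω1 price and its single-end contraction cost.

    The window defaults to MaxLength / 2 residues from either terminus;
    intersections outside it are returned unchanged.
    """
    if window is None:
        window = max_length / 2.0
    L = float(morph.m)
    near_n = (si.a - 1.0) <= window
    near_c = (L - si.b) <= window
    if not (near_n or near_c):
        return omega1
    costs = []
    if near_n:
        c, _ = _n_contraction_cost(morph, si.a, use_estimates)
        costs.append(c)
    if near_c:
        c, _ = _c_contraction_cost(morph, si.b, use_estimates)
        costs.append(c)
    contraction_price = min(costs)
    omega1_price = omega1.price if omega1.feasible else math.inf
    price = min(omega1_price, contraction_price)
    if price is math.inf:
        return omega1
    return MoveCandidate(
        kind="omega1",
        members=list(omega1.members),
        backbone_length=omega1.backbone_length,
        price=float(price),
        feasible=True,
        blocking=None if omega1.feasible else "priced as end-contraction",
        writhe_jump=omega1.writhe_jump,
    )
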