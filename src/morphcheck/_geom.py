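"""Low-level 3D geometry predicates shared by the move/obstruction modules.

All routines operate on numpy float arrays of shape (3,) unless stated
otherwise.  Tolerances are absolute and expressed in the coordinate units
(Ångström throughout the package).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "segment_segment_distance",
    "segment_triangle_intersect",
    "point_line_distance",
    "point_segment_distance",
]


def segment_segment_distance(p0, p1, q0, q1):
    """Minimum distance between segments [p0,p1] and [q0,q1].

    Clamped closed-form solution of the quadratic in the two segment
    parameters (Eberly's robust formulation).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    q0 = np.asarray(q0, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    tiny = 1e-14
    if a <= tiny and e <= tiny:
        return float(np.linalg.norm(r))
    if a <= tiny:
        s = 0.0
        t = np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= tiny:
            t = 0.0
            s = np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            if denom > tiny * a * e:
                s = np.clip((b * f - c * e) / denom, 0.0, 1.0)
            else:  # nearly parallel
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t = 1.0
                s = np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p0 + s * d1
    closest2 = q0 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


def _point_in_triangle_2d(p, a, b, c, eps):
    """Barycentric containment test in 2D with absolute slack ``eps``."""

    def cross(o, u, v):
        return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])

    d1 = cross(a, b, p)
    d2 = cross(b, c, p)
    d3 = cross(c, a, p)
    has_neg = (d1 < -eps) or (d2 < -eps) or (d3 < -eps)
    has_pos = (d1 > eps) or (d2 > eps) or (d3 > eps)
    return not (has_neg and has_pos)


def segment_triangle_intersect(p, q, t0, t1, t2, eps=1e-9):
    """True if segment [p,q] intersects triangle (t0,t1,t2).

    Degenerate (zero-area) triangles report no intersection; a segment
    lying (almost) in the triangle plane is tested by 2D overlap against
    the triangle edges and interior.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)

    e1 = t1 - t0
    e2 = t2 - t0
    n = np.cross(e1, e2)
    n_norm = float(np.linalg.norm(n))
    if n_norm < 1e-12:
        return False  # degenerate triangle: skipped by convention
    n = n / n_norm

    dp = float(n @ (p - t0))
    dq = float(n @ (q - t0))

    if abs(dp) < eps and abs(dq) < eps:
        # Coplanar: project to the dominant triangle plane and test in 2D.
        axis = int(np.argmax(np.abs(np.cross(e1, e2))))
        keep = [i for i in range(3) if i != axis]
        a2, b2, c2 = t0[keep], t1[keep], t2[keep]
        p2, q2 = p[keep], q[keep]
        if _point_in_triangle_2d(p2, a2, b2, c2, eps):
            return True
        if _point_in_triangle_2d(q2, a2, b2, c2, eps):
            return True
        # segment vs each triangle edge in 2D
        for (u, v) in ((a2, b2), (b2, c2), (c2, a2)):
            if _segments_intersect_2d(p2, q2, u, v, eps):
                return True
        return False

    if dp > eps and dq > eps:
        return False
    if dp < -eps and dq < -eps:
        return False

    denom = dp - dq
    if abs(denom) < 1e-15:
        return False
    s = dp / denom  # parameter along [p, q] of the plane crossing
    if s < -eps or s > 1.0 + eps:
        return False
    x = p + s * (q - p)
    # barycentric containment of x
    v0 = e1
    v1 = e2
    v2 = x - t0
    d00 = float(v0 @ v0)
    d01 = float(v0 @ v1)
    d11 = float(v1 @ v1)
    d20 = float(v2 @ v0)
    d21 = float(v2 @ v1)
    den = d00 * d11 - d01 * d01
    if abs(den) < 1e-15:
        return False
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    u = 1.0 - v - w
    slack = eps * max(1.0, abs(den)) / max(abs(den), 1e-15)
    return (u >= -slack) and (v >= -slack) and (w >= -slack)


def _segments_intersect_2d(p, q, u, v, eps):
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(u, v, p)
    d2 = cross(u, v, q)
    d3 = cross(p, q, u)
    d4 = cross(p, q, v)
    if ((d1 > eps and d2 < -eps) or (d1 < -eps and d2 > eps)) and (
        (d3 > eps and d4 < -eps) or (d3 < -eps and d4 > eps)
    ):
        return True
    return False


def point_line_distance(point, line_a, line_b):
    """Distance from ``point`` to the infinite line through ``line_a``/``line_b``.

    Falls back to point-point distance when the two line anchors coincide.
    """
    point = np.asarray(point, dtype=float)
    line_a = np.asarray(line_a, dtype=float)
    line_b = np.asarray(line_b, dtype=float)
    d = line_b - line_a
    L = float(np.linalg.norm(d))
    if L < 1e-12:
        return float(np.linalg.norm(point - line_a))
    return float(np.linalg.norm(np.cross(point - line_a, d)) / L)


def point_segment_distance(point, seg_a, seg_b):
    point = np.asarray(point, dtype=float)
    seg_a = np.asarray(seg_a, dtype=float)
    seg_b = np.asarray(seg_b, dtype=float)
    d = seg_b - seg_a
    L2 = float(d @ d)
    if L2 < 1e-14:
        return float(np.linalg.norm(point - seg_a))
    t = np.clip(float((point - seg_a) @ d) / L2, 0.0, 1.0)
    return float(np.linalg.norm(point - (seg_a + t * d)))
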