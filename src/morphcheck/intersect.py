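"""Transversal self-intersections of the linear morph.

Two non-adjacent segments i and j can pass through each other at times t*
where the determinant

    det_ij(t) = det( P_{i+1}(t)-P_i(t),  P_{j+1}(t)-P_j(t),  P_i(t)-P_j(t) )

vanishes.  det_ij is a cubic in t because each column is linear in t.  At an
isolated real root in [0, 1] the two segments are coplanar; they actually
intersect iff the planar 2-unknown system

    (1-s_i) P_i(t*) + s_i P_{i+1}(t*) = (1-s_j) P_j(t*) + s_j P_{j+1}(t*)

has a solution with s_i, s_j in [0, 1].  The crossing-sign change is the sign
of d/dt det_ij at t*; roots where that derivative (on the max-normalized
polynomial) is below tolerance are tangential, not transversal, and are
discarded but counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .morphgeo import Morph
from .overlap import OverlapResult, needs_intersection_check

__all__ = ["SelfIntersection", "Diagnostics", "det_cubic", "find_intersections"]

ROOT_TOL = 1e-9  # on the max-normalized cubic
CONTAIN_SLACK = 1e-9  # slack on s_i, s_j in [0, 1]

# Vandermonde nodes for exact degree-3 interpolation of the determinant
_NODES = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
_VINV = np.linalg.inv(np.vander(_NODES, 4))  # coeffs highest power first


@dataclass
class SelfIntersection:
    """One transversal event: curve parameters a < b (1-based, in [1, m]),
    its sign change and morph time t*."""

    a: float
    b: float
    sign: int
    t_star: float
    seg_i: int = 0  # 0-based segment indices
    seg_j: int = 0
    k: int = -1
    alignment_class: str = ""
    boundary: bool = False


@dataclass
class Diagnostics:
    pairs_checked: int = 0
    pairs_skipped: int = 0
    tangential_discarded: int = 0


def det_cubic(morph: Morph, i: int, j: int) -> np.ndarray:
    """Coefficients (highest power first, length 4) of det_ij(t) for 0-based
    non-adjacent segments i and j."""
    if abs(i - j) < 2:
        raise ValueError("segments must be non-adjacent (|i-j| >= 2)")
    vals = np.empty(4)
    for k, t in enumerate(_NODES):
        p = morph.slice_at(t)
        vals[k] = np.linalg.det(
            np.column_stack((p[i + 1] - p[i], p[j + 1] - p[j], p[i] - p[j]))
        )
    return _VINV @ vals


def _real_roots_in_unit(coeffs: np.ndarray):
    """Isolated real roots of the cubic in [0, 1], Newton-polished.

    Returns (roots, n_tangential) where tangential means the normalized
    derivative at the root is below tolerance (double roots / constant-zero).
    """
    scale = float(np.max(np.abs(coeffs)))
    if scale < 1e-300:
        return [], 0  # identically zero: permanently coplanar, no transversal event
    c = coeffs / scale
    nz = np.nonzero(np.abs(c) > 1e-13)[0]
    if len(nz) == 0:
        return [], 0
    c_trim = c[nz[0] :]
    if len(c_trim) == 1:
        return [], 0  # nonzero constant: no roots
    raw = np.roots(c_trim)
    dc = np.polyder(c)
    roots = []
    n_tangential = 0
    for r in raw:
        if abs(r.imag) > 1e-7:
            continue
        t = float(r.real)
        if t < -1e-3 or t > 1.0 + 1e-3:
            continue
        # Newton polish on the normalized cubic
        for _ in range(50):
            f = np.polyval(c, t)
            fp = np.polyval(dc, t)
            if abs(fp) < 1e-14:
                break
            step = f / fp
            t -= step
            if abs(step) < 1e-15:
                break
        if not (-ROOT_TOL <= t <= 1.0 + ROOT_TOL):
            continue
        if abs(np.polyval(c, t)) > 1e-6:
            continue
        if any(abs(t - t0) < 1e-7 for t0, _ in roots):
            n_tangential += 1  # coincident (double) root
            continue
        deriv = float(np.polyval(dc, t))
        if abs(deriv) < ROOT_TOL:
            n_tangential += 1
            continue
        roots.append((t, int(np.sign(deriv))))
    return roots, n_tangential


def _planar_solve(p, i, j):
    """Solve the coplanar 2-unknown system for (s_i, s_j) at a t-slice p."""
    u = p[i + 1] - p[i]
    v = p[j + 1] - p[j]
    rhs = p[j] - p[i]
    A = np.column_stack((u, -v))
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    s_i, s_j = float(sol[0]), float(sol[1])
    residual = float(np.linalg.norm(A @ sol - rhs))
    return s_i, s_j, residual


def find_intersections(
    morph: Morph,
    overlaps: Optional[OverlapResult] = None,
    diagnostics: Optional[Diagnostics] = None,
) -> List[SelfIntersection]:
    """All transversal self-intersections of the morph, sorted by (t*, a, b).

    When ``overlaps`` is given, segment pairs whose endpoint spacings and
    4-term overlap sums prove no intersection can occur are skipped; this
    filter is sound (it never removes a true intersection).
    """
    diag = diagnostics if diagnostics is not None else Diagnostics()
    m = morph.m
    found: List[SelfIntersection] = []
    scale = max(
        float(np.abs(morph.curve0).max()), float(np.abs(morph.curve1).max()), 1.0
    )
    for i in range(m - 1):
        for j in range(i + 2, m - 1):
            if overlaps is not None and not needs_intersection_check(
                i, j, overlaps, morph
            ):
                diag.pairs_skipped += 1
                continue
            diag.pairs_checked += 1
            coeffs = det_cubic(morph, i, j)
            roots, n_tan = _real_roots_in_unit(coeffs)
            diag.tangential_discarded += n_tan
            for t_star, sgn in roots:
                t_eval = min(max(t_star, 0.0), 1.0)
                p = morph.slice_at(t_eval)
                s_i, s_j, residual = _planar_solve(p, i, j)
                if residual > 1e-5 * scale:
                    continue  # inconsistent: segments coplanar but disjoint lines
                if not (
                    -CONTAIN_SLACK <= s_i <= 1.0 + CONTAIN_SLACK
                    and -CONTAIN_SLACK <= s_j <= 1.0 + CONTAIN_SLACK
                ):
                    continue
                boundary = bool(t_star < ROOT_TOL or t_star > 1.0 - ROOT_TOL)
                found.append(
                    SelfIntersection(
                        a=(i + 1) + min(max(s_i, 0.0), 1.0),
                        b=(j + 1) + min(max(s_j, 0.0), 1.0),
                        sign=sgn,
                        t_star=t_eval,
                        seg_i=i,
                        seg_j=j,
                        boundary=boundary,
                    )
                )
    found.sort(key=lambda s: (s.t_star, s.a, s.b))
    for k, s in enumerate(found):
        s.k = k
    return found
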