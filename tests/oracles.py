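"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by a route deliberately different from the
implementation: dense sampling plus bisection instead of closed-form cubic
roots, grid minimization plus golden-section polish instead of the analytic
t*, unsorted all-pairs scans instead of distance-sorted early stopping, and
exhaustive matching enumeration instead of blossom matching.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from morphcheck._geom import segment_segment_distance, segment_triangle_intersect


def grid_pair_min_distance(p0i, p0j, p1i, p1j, step=1e-4):
    """min_t |p^j(t) - p^i(t)| by dense grid + bounded golden-section polish."""
    rel0 = np.asarray(p0j, float) - np.asarray(p0i, float)
    rel1 = np.asarray(p1j, float) - np.asarray(p1i, float)

    def d(t):
        v = (1 - t) * rel0 + t * rel1
        return float(np.linalg.norm(v))

    ts = np.arange(0.0, 1.0 + step, step)
    vals = np.linalg.norm((1 - ts)[:, None] * rel0 + ts[:, None] * rel1, axis=1)
    k = int(np.argmin(vals))
    lo = max(ts[k] - step, 0.0)
    hi = min(ts[k] + step, 1.0)
    res = minimize_scalar(d, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return min(float(res.fun), float(vals[k]))


def _det_at(morph, i, j, ts):
    """Numeric det_ij over an array of times (no polynomial fitting)."""
    c0, c1 = morph.curve0, morph.curve1
    ts = np.asarray(ts, float)[:, None]
    u = (1 - ts) * (c0[i + 1] - c0[i]) + ts * (c1[i + 1] - c1[i])
    v = (1 - ts) * (c0[j + 1] - c0[j]) + ts * (c1[j + 1] - c1[j])
    w = (1 - ts) * (c0[i] - c0[j]) + ts * (c1[i] - c1[j])
    return np.einsum("ij,ij->i", np.cross(u, v), w)


def sampled_intersections(morph, step=1e-4):
    """Self-intersections by dense time sampling: track sign changes of the
    numeric determinant, bisect each to machine precision, and accept the
    event iff the two segments actually meet (distance < 1e-6 Å) there.

    Returns a list of (a, b, sign, t*) tuples sorted by (t*, a, b).
    """
    m = morph.m
    ts = np.arange(0.0, 1.0 + step, step)
    found = []
    for i in range(m - 1):
        for j in range(i + 2, m - 1):
            dets = _det_at(morph, i, j, ts)
            sgn = np.sign(dets)
            flips = np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]
            for k in flips:
                lo, hi = ts[k], ts[k + 1]
                flo = dets[k]
                for _ in range(80):
                    mid = 0.5 * (lo + hi)
                    fmid = _det_at(morph, i, j, [mid])[0]
                    if flo * fmid <= 0:
                        hi = mid
                    else:
                        lo, flo = mid, fmid
                t_root = 0.5 * (lo + hi)
                p = morph.slice_at(t_root)
                dist = segment_segment_distance(
                    p[i], p[i + 1], p[j], p[j + 1]
                )
                if dist >= 1e-6:
                    continue
                # locate the meeting point parameters from the closest points
                a_par, b_par = _meeting_params(p, i, j)
                slope = (
                    _det_at(morph, i, j, [min(t_root + 1e-7, 1.0)])[0]
                    - _det_at(morph, i, j, [max(t_root - 1e-7, 0.0)])[0]
                )
                found.append((a_par, b_par, int(np.sign(slope)), t_root))
    found.sort(key=lambda x: (x[3], x[0], x[1]))
    return found


def _meeting_params(p, i, j):
    u = p[i + 1] - p[i]
    v = p[j + 1] - p[j]
    A = np.column_stack((u, -v))
    sol, *_ = np.linalg.lstsq(A, p[j] - p[i], rcond=None)
    return (i + 1) + float(np.clip(sol[0], 0, 1)), (j + 1) + float(
        np.clip(sol[1], 0, 1)
    )


def brute_disk_is_free(disk, curve, excluded):
    """Unsorted all-pairs segment-triangle scan (no early stopping)."""
    import math

    curve = np.asarray(curve, float)
    tris = list(disk.triangles())
    for seg in range(len(curve) - 1):
        lo_p, hi_p = seg + 1, seg + 2
        skip = False
        for (a, b) in excluded:
            if not (hi_p <= math.floor(a) or lo_p >= math.ceil(b)):
                skip = True
                break
        if skip:
            continue
        for (t0, t1, t2) in tris:
            if segment_triangle_intersect(curve[seg], curve[seg + 1], t0, t1, t2):
                return False
    return True


def enumerate_matchings(edges):
    """All matchings (as frozensets of edges) of an edge list."""
    if not edges:
        return [frozenset()]
    first, rest = edges[0], edges[1:]
    without = enumerate_matchings(rest)
    u, v = first
    compatible = [e for e in rest if u not in e and v not in e]
    with_first = [m | {first} for m in enumerate_matchings(compatible)]
    return without + with_first


def brute_essential_optimum(vertices, omega1_feasible, omega1_price, edges,
                            edge_price):
    """Exhaustive (N, price) optimum over all matchings, independent of the
    weight construction: N counts unmatched non-Ω1 vertices; the price sums
    used Ω2 edges and the Ω1 moves of unmatched Ω1-feasible vertices."""
    best = None
    for matching in enumerate_matchings(list(edges)):
        matched = set()
        for (u, v) in matching:
            matched.update((u, v))
        N = sum(
            1 for k in vertices if k not in matched and not omega1_feasible[k]
        )
        price = sum(edge_price[e] for e in matching) + sum(
            omega1_price[k]
            for k in vertices
            if k not in matched and omega1_feasible[k]
        )
        if best is None or (N, price) < best:
            best = (N, price)
    return best
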