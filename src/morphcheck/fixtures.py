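"""Deterministic synthetic chain pairs exercising every analysis surface.

All generators are closed-form (no randomness beyond an optional seed for
tail jitter-free layouts) and clash-free at both morph endpoints under the
alpha d_min table.  They emulate the geometric situations the method is
designed for — a crossing change between otherwise identical structures,
loops removable or blocked for Ω1, and a strand slide producing an Ω2 pair —
not physically realistic protein decoys.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

from .chain_io import AlignmentRecord, Chain

__all__ = [
    "make_crossing_change_pair",
    "make_loop_fixtures",
    "make_worked_alignment",
    "worked_alignment_text",
    "chain_to_pdb",
    "CA_SPACING",
]

CA_SPACING = 3.8  # Å, typical CA-CA distance
# z-heights of the over-crossing strand; the under strand is the negation
CROSS_HEIGHTS = np.array([0.0, 0.0, 1.25, 2.5, 2.5, 1.25, 0.0, 0.0])
LANE_SEP = 4  # serpentine lane separation in grid units (4 * 3.8 = 15.2 Å)


def _serpentine(start_xy, n, direction, lane_axis, lane_len=12):
    """Clash-free serpentine tail on the 3.8 Å grid, in the half-plane
    pointed to by ``direction`` along ``lane_axis`` (0=x, 1=y)."""
    pts = []
    x, y = start_xy
    step = direction
    along = lane_axis
    pos = [x, y]
    remaining = n
    while remaining > 0:
        for _ in range(lane_len):
            if remaining == 0:
                break
            pos[along] += step
            pts.append((pos[0], pos[1]))
            remaining -= 1
        if remaining == 0:
            break
        # 3-point turn to the next lane, LANE_SEP grid units away
        other = 1 - along
        for frac in (LANE_SEP / 3.0, LANE_SEP / 3.0, LANE_SEP / 3.0):
            if remaining == 0:
                break
            pos[other] += frac
            pts.append((pos[0], pos[1]))
            remaining -= 1
        step = -step
    return pts


def make_crossing_change_pair(n: int = 100) -> Tuple[Chain, Chain]:
    """Two n-point chains identical except that the central over- and
    under-crossing strands swap (z-heights negated between the structures).

    The over strand runs along x with heights 0, 0, 1.25, 2.5, 2.5, 1.25,
    0, 0 Å; the under strand crosses it along y at the negated heights.  The
    total motion is 4 residues traveling 5 Å and 4 traveling 2.5 Å, so for
    n >= 100 the pair scores like near-identical structures while the morph
    must pass the backbone through itself exactly once.
    """
    if n < 24:
        raise ValueError("crossing-change fixture needs n >= 24")
    # strand A (over) along x at y = 0; apex between x = -1 and 0
    ax = [(-4 + k, 0.0) for k in range(8)]
    # connector from A's end (3, 0) around to B's start (-0.5, -4.5)
    connector = [
        (4.0, 0.0),
        (5.0, -0.6),
        (5.3, -1.8),
        (5.3, -3.0),
        (4.9, -4.2),
        (4.0, -5.1),
        (2.7, -5.6),
        (1.3, -5.7),
    ]
    # strand B (under) along y at x = -0.5; apex between y = -1.5 and -0.5
    bx = [(-0.5, -4.5 + k) for k in range(8)]
    core = ax + connector + bx

    extra = n - len(core)
    n_tail = (extra + 1) // 2
    c_tail = extra - n_tail
    # N-tail heads west from A's start (-4, 0); C-tail heads north from
    # B's end (-0.5, 2.5); both serpentine away from the crossing region
    tail_n = _serpentine((-4.0, 0.0), n_tail, direction=-1, lane_axis=0)[::-1]
    tail_c = _serpentine((-0.5, 2.5), c_tail, direction=+1, lane_axis=1)

    xy = np.array(tail_n + core + tail_c, dtype=float) * CA_SPACING
    z0 = np.zeros(n)
    z1 = np.zeros(n)
    a_start = n_tail
    b_start = n_tail + 8 + len(connector)
    z0[a_start : a_start + 8] = CROSS_HEIGHTS
    z0[b_start : b_start + 8] = -CROSS_HEIGHTS
    z1[a_start : a_start + 8] = -CROSS_HEIGHTS
    z1[b_start : b_start + 8] = CROSS_HEIGHTS

    p0 = np.column_stack([xy, z0])
    p1 = np.column_stack([xy, z1])
    return (
        Chain(points=p0, source_id="crossing_change_0"),
        Chain(points=p1, source_id="crossing_change_1"),
    )


def _loop_core():
    """Shared geometry of the loop fixtures: an entry strand crossing an exit
    strand under an 11-point loop arc (radius 7 Å, 30° steps, fine enough to
    stay put under smoothening).  Returns (points, mobile_slice) where the
    mobile points' z-coordinates are negated in structure 1."""
    entry = [(-17.94, -10.14, 1.0), (-12.97, -7.57, 1.0)]
    # the z-negated part: entry segment, loop arc, exit segment
    mobile = [(-8.0, -5.0, 1.0)]
    r, cx, cy = 7.0, 0.0, 7.0
    z_lo, z_hi = -2.5, 2.5
    angles = [-60 + 30 * k for k in range(11)]  # -60 .. 240 degrees
    loop = []
    for idx, ang in enumerate(angles):
        th = math.radians(ang)
        z = z_hi - (z_hi - z_lo) * idx / 10.0
        loop.append((cx + r * math.cos(th), cy + r * math.sin(th), z))
    mobile.extend(loop)
    mobile.append((8.0, -5.0, -1.0))
    exit_tail = [(12.97, -7.57, -1.0), (17.94, -10.14, -1.0)]
    pts = entry + mobile + exit_tail
    mobile_slice = slice(len(entry), len(entry) + len(mobile))
    return pts, mobile_slice


def make_loop_fixtures(kind: str, seed: int = 0) -> Tuple[Chain, Chain]:
    """Loop test pairs.

    removable_loop
        mirrored-handedness loops whose morph has one self-intersection with
        an isolated spanning disk (Ω1-feasible).
    threaded_loop
        the same with a static strand threading the disk (Ω1-infeasible).
    slide_pair
        a V-shaped strand slid across a straight one, producing two
        opposite-sign self-intersections at the same time (Ω2-feasible).
    """
    if kind in ("removable_loop", "threaded_loop"):
        pts, mobile = _loop_core()
        if kind == "threaded_loop":
            # a static strand piercing the loop's spanning disk near its
            # centroid, routed well clear of everything else
            thread = [
                (14.0, -2.0, -4.5),
                (10.0, 2.0, -6.0),
                (5.5, 7.0, -6.0),
                (0.0, 7.0, -6.0),
                (0.0, 7.0, 6.0),
                (-4.5, 9.5, 6.0),
                (-9.0, 12.0, 6.0),
            ]
            pts = pts + thread
        p0 = np.array(pts, dtype=float)
        p1 = p0.copy()
        p1[mobile, 2] = -p1[mobile, 2]
        return (
            Chain(points=p0, source_id=f"{kind}_0"),
            Chain(points=p1, source_id=f"{kind}_1"),
        )
    if kind == "slide_pair":
        # straight static strand S along x, then a V-shaped strand that dips
        # below S's height and slides from y = +6 to y = -6; the connecting
        # route stays above everything so the only morph events are the two
        # V-arm crossings of S (both at t* = 0.5)
        static = [(-8.0, 0.0, 0.0), (-4.0, 0.0, 0.0), (0.0, 0.0, 0.0),
                  (4.0, 0.0, 0.0), (8.0, 0.0, 0.0), (12.0, 0.0, 6.0)]
        route0 = [(12.0, 6.0, 7.0), (-3.0, 6.0, 8.0)]
        route1 = [(12.0, -6.0, 7.0), (-3.0, -6.0, 8.0)]
        v0 = [(-3.0, 6.0, 2.0), (0.0, 6.0, -2.0), (3.0, 6.0, 2.0)]
        v1 = [(-3.0, -6.0, 2.0), (0.0, -6.0, -2.0), (3.0, -6.0, 2.0)]
        p0 = np.array(static + route0 + v0, dtype=float)
        p1 = np.array(static + route1 + v1, dtype=float)
        return (
            Chain(points=p0, source_id="slide_pair_0"),
            Chain(points=p1, source_id="slide_pair_1"),
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


# the 12-residue / 10-residue gapped-alignment worked example
_WORKED_PAIRS = [(3, 1), (4, 2), (6, 3), (7, 4), (10, 8), (11, 9)]


def make_worked_alignment() -> AlignmentRecord:
    """The 12-vs-10-residue gapped alignment whose reparameterization is
    RePar0 = [3,4,5,6,7,7.75,8.5,9.25,10,11], RePar1 = [1,2,2.5,3,4,5,6,7,8,9];
    its first aligned column is the weak (".") pair."""
    weak = [True] + [False] * (len(_WORKED_PAIRS) - 1)
    return AlignmentRecord(
        pairs=list(_WORKED_PAIRS), weak_flags=weak, len0=12, len1=10,
        method="tm_align",
    )


def worked_alignment_text() -> str:
    """The worked example as a TM-align three-line block.

    Columns 1-2: chain-0 overhang; 3-4 aligned (3 weak); 5: residue 5 vs a
    gap; 6-7 aligned; 8-12: the 3-vs-4-interval gap block; 13-14 aligned;
    15: unaligned terminal pair.
    """
    seq0 = "AAAAAAAAA---AAA"
    mark = "  .: ::     :: "
    seq1 = "--AA-AA--AAAAAA"
    return "\n".join((seq0, mark, seq1)) + "\n"


def chain_to_pdb(chain: Chain, chain_id: str = "A") -> str:
    """Render a CA trace as minimal PDB text (for end-to-end CLI tests)."""
    lines = []
    for i, (x, y, z) in enumerate(chain.points, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  GLY {chain_id}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
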