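"""Gap reparameterization: equal-length curve parameter lists and IsAligned.

A gapped residue alignment is converted into two strictly increasing lists of
real curve parameters RePar0/RePar1 of common length m.  Between consecutive
aligned pairs spanning g0 intervals on chain 0 and g1 on chain 1, max(g0, g1)
uniform steps are inserted so both curves reach the next aligned pair
simultaneously; the curves are then evaluated at these (possibly fractional)
parameters by piecewise-linear interpolation.

IsAligned is 1 at vertices that are aligned pairs and 0 at inserted
(gap-filling) vertices, and is interpolated linearly along segments.  The
Aligned Window Fraction (AWF) is the shorter aligned window length divided by
the shorter chain length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .chain_io import AlignmentRecord, Chain

__all__ = [
    "ReparamPair",
    "build_reparam",
    "eval_curve",
    "interpolated_dmin",
    "classify_intersection_alignment",
    "is_aligned_at",
    "DMIN_ALPHA",
    "DMIN_SMOOTH",
]

# Minimal CA-CA distances (Å) by backbone separation, estimated from native
# structures; index 0 <-> separation 1.  Beyond the table the value is constant.
DMIN_ALPHA = (2.8, 4.5, 3.86, 3.47, 3.52, 3.48, 3.6, 3.7)
DMIN_SMOOTH = (1.0, 2.1, 3.0, 3.4, 3.6, 3.7)


@dataclass
class ReparamPair:
    """Equal-length reparameterizations of the two aligned curves."""

    repar0: np.ndarray
    repar1: np.ndarray
    is_aligned: np.ndarray  # 0/1 at vertices
    awf: float

    def __post_init__(self):
        self.repar0 = np.asarray(self.repar0, dtype=float)
        self.repar1 = np.asarray(self.repar1, dtype=float)
        self.is_aligned = np.asarray(self.is_aligned, dtype=float)
        m = len(self.repar0)
        if not (len(self.repar1) == len(self.is_aligned) == m):
            raise ValueError("reparameterization lists must share a length")
        if np.any(np.diff(self.repar0) <= 0) or np.any(np.diff(self.repar1) <= 0):
            raise ValueError("reparameterizations must be strictly increasing")

    @property
    def m(self) -> int:
        return len(self.repar0)


def build_reparam(alignment: AlignmentRecord) -> ReparamPair:
    """Fill alignment gaps by uniform-step linear interpolation.

    Weak (".") pairs count as aligned.  Unaligned terminal overhangs outside
    the aligned window are excluded from the reparameterized curves.
    """
    pairs = alignment.pairs
    if len(pairs) < 2:
        raise ValueError("need at least 2 aligned pairs")
    r0 = [float(pairs[0][0])]
    r1 = [float(pairs[0][1])]
    flags = [1.0]
    for (a0, a1), (b0, b1) in zip(pairs[:-1], pairs[1:]):
        g0 = b0 - a0
        g1 = b1 - a1
        if g0 <= 0 or g1 <= 0:
            raise ValueError("alignment pairs must be strictly monotone")
        steps = max(g0, g1)
        for s in range(1, steps + 1):
            r0.append(a0 + g0 * s / steps)
            r1.append(a1 + g1 * s / steps)
            flags.append(1.0 if s == steps else 0.0)
    window0 = pairs[-1][0] - pairs[0][0] + 1
    window1 = pairs[-1][1] - pairs[0][1] + 1
    shorter_chain = min(alignment.len0, alignment.len1)
    awf = min(window0, window1) / shorter_chain
    return ReparamPair(
        repar0=np.array(r0),
        repar1=np.array(r1),
        is_aligned=np.array(flags),
        awf=float(awf),
    )


def eval_curve(chain, s) -> np.ndarray:
    """Evaluate the piecewise-linear curve at parameter(s) ``s`` in [1, n].

    ``chain`` may be a Chain or a raw (n, 3) point array.  Vectorized over s.
    """
    points = chain.points if isinstance(chain, Chain) else np.asarray(chain, float)
    n = len(points)
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 1.0 - 1e-9) or np.any(s_arr > n + 1e-9):
        raise ValueError(f"curve parameter outside [1, {n}]")
    s_clipped = np.clip(s_arr, 1.0, n)
    idx = np.clip(np.floor(s_clipped).astype(int), 1, n - 1)
    frac = s_clipped - idx
    out = (1.0 - frac)[..., None] * points[idx - 1] + frac[..., None] * points[idx]
    if s_arr.ndim == 0:
        return out.reshape(3)
    return out


def interpolated_dmin(separation, table: Sequence[float] = DMIN_ALPHA):
    """d_min at a (possibly fractional) backbone separation, by linear
    interpolation of the discrete table; constant beyond the last entry.

    Vectorized over ``separation``.
    """
    table = np.asarray(table, dtype=float)
    s = np.asarray(separation, dtype=float)
    if np.any(s <= 0):
        raise ValueError("separation must be positive")
    grid = np.arange(1, len(table) + 1, dtype=float)
    out = np.interp(s, grid, table)  # np.interp clamps outside the grid
    if np.ndim(separation) == 0:
        return float(out)
    return out


def is_aligned_at(rp: ReparamPair, a) -> float:
    """IsAligned at curve parameter ``a`` (linear interpolation on segments)."""
    a_arr = np.asarray(a, dtype=float)
    grid = np.arange(1, rp.m + 1, dtype=float)
    out = np.interp(a_arr, grid, rp.is_aligned)
    if a_arr.ndim == 0:
        return float(out)
    return out


def classify_intersection_alignment(si, rp: ReparamPair) -> str:
    """Classify by AlignedSum = IsAligned(a_k) + IsAligned(b_k).

    >= 1.5 -> "aligned_aligned"; (0.5, 1.5) -> "aligned_gap";
    <= 0.5 -> "gap_gap".  Boundaries are inclusive toward the stronger class.
    """
    s = is_aligned_at(rp, si.a) + is_aligned_at(rp, si.b)
    if s >= 1.5:
        return "aligned_aligned"
    if s > 0.5:
        return "aligned_gap"
    return "gap_gap"
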