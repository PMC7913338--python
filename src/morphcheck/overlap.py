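"""Steric overlap of the linear interpolation.

For vertices i < j the squared pair distance during the morph,

    d_ij^2(t) = (1-t)^2 a^2 + t^2 b^2 + 2 t (1-t) a b cos(theta),

with a = |p0^ij|, b = |p1^ij|, is minimized in closed form at

    t* = (a^2 - a b cos(theta)) / (a^2 + b^2 - 2 a b cos(theta)),

clamped to [0, 1].  The overlap of a pair is the violation of the native
minimum-distance table: max(d_min(sep) - d_interp, 0), penalized linearly,
and MeanOverlap is the chain-normalized sum (1/n) sum_{i<j} overlap_ij.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .morphgeo import Morph
from .reparam import DMIN_ALPHA, DMIN_SMOOTH, ReparamPair, interpolated_dmin

__all__ = [
    "PairTrack",
    "OverlapResult",
    "pair_min_distance",
    "overlap_analysis",
    "needs_intersection_check",
    "SKIP_THRESHOLDS",
]

# representation -> (neighbor spacing bound Å, 4-term overlap sum bound Å)
SKIP_THRESHOLDS = {"alpha": (4.0, 2.6), "smooth": (3.5, 2.1)}

LOCAL_SEPARATION = 4  # |i-j| <= 4 counts as local overlap


@dataclass
class PairTrack:
    """Closed-form minimum-distance record for one vertex pair."""

    i: int
    j: int
    a: float
    b: float
    cos_theta: float
    t_star: Optional[float]  # None on the degenerate (constant-distance) branch
    t_tilde: float
    d_interp: float
    overlap: float = 0.0


def pair_min_distance(p0i, p0j, p1i, p1j, i: int = 0, j: int = 0,
                      d_min: float = 0.0) -> PairTrack:
    """Minimum distance between morphing points i and j over t in [0, 1].

    If the relative vector does not change during the morph the distance is
    constant and t_tilde is fixed at 0 by convention.
    """
    rel0 = np.asarray(p0j, float) - np.asarray(p0i, float)
    rel1 = np.asarray(p1j, float) - np.asarray(p1i, float)
    a = float(np.linalg.norm(rel0))
    b = float(np.linalg.norm(rel1))
    diff = rel1 - rel0
    den = float(diff @ diff)
    dot = float(rel0 @ rel1)
    cos_theta = dot / (a * b) if a > 0 and b > 0 else 1.0
    if den < 1e-14:
        t_star = None
        t_tilde = 0.0
        d_interp = a
    else:
        t_star = (a * a - dot) / den
        t_tilde = min(max(t_star, 0.0), 1.0)
        d2 = (
            (1 - t_tilde) ** 2 * a * a
            + t_tilde**2 * b * b
            + 2 * t_tilde * (1 - t_tilde) * dot
        )
        d_interp = float(np.sqrt(max(d2, 0.0)))
    return PairTrack(
        i=i,
        j=j,
        a=a,
        b=b,
        cos_theta=cos_theta,
        t_star=t_star,
        t_tilde=t_tilde,
        d_interp=d_interp,
        overlap=max(d_min - d_interp, 0.0),
    )


@dataclass
class OverlapResult:
    """Pairwise overlap of a morph.

    ``overlap_matrix`` and ``d_interp_matrix`` are dense symmetric (m, m)
    arrays over 0-based vertex indices (zero on and below the diagonal of the
    stored upper triangle's mirror).
    """

    overlap_matrix: np.ndarray
    d_interp_matrix: np.ndarray
    mean_overlap: float
    local_overlap: float
    nonlocal_overlap: float
    table: Sequence[float]
    representation: str = "alpha"

    @property
    def total_overlap(self) -> float:
        return self.local_overlap + self.nonlocal_overlap


def _dmin_for_pairs(iu, ju, repar: Optional[ReparamPair], table):
    if repar is None:
        sep = (ju - iu).astype(float)
        return interpolated_dmin(sep, table)
    sep0 = repar.repar0[ju] - repar.repar0[iu]
    sep1 = repar.repar1[ju] - repar.repar1[iu]
    # the weakest of the two per-curve constraints binds
    return np.minimum(
        interpolated_dmin(sep0, table), interpolated_dmin(sep1, table)
    )


def overlap_analysis(
    morph: Morph,
    table: Optional[Sequence[float]] = None,
    repar: Optional[ReparamPair] = None,
) -> OverlapResult:
    """Overlap of every vertex pair i < j of the morph.

    ``table`` defaults to the d_min table matching the morph representation.
    When ``repar`` is given, backbone separations are measured in original
    curve units through the reparameterization and d_min is interpolated.
    """
    if table is None:
        table = DMIN_ALPHA if morph.representation == "alpha" else DMIN_SMOOTH
    m = morph.m
    iu, ju = np.triu_indices(m, k=1)
    rel0 = morph.curve0[ju] - morph.curve0[iu]
    rel1 = morph.curve1[ju] - morph.curve1[iu]
    a2 = np.einsum("ij,ij->i", rel0, rel0)
    b2 = np.einsum("ij,ij->i", rel1, rel1)
    dot = np.einsum("ij,ij->i", rel0, rel1)
    diff = rel1 - rel0
    den = np.einsum("ij,ij->i", diff, diff)
    degenerate = den < 1e-14
    t_star = np.where(degenerate, 0.0, (a2 - dot) / np.where(degenerate, 1.0, den))
    t_tilde = np.clip(t_star, 0.0, 1.0)
    d2 = (
        (1 - t_tilde) ** 2 * a2
        + t_tilde**2 * b2
        + 2 * t_tilde * (1 - t_tilde) * dot
    )
    d_interp = np.sqrt(np.maximum(np.where(degenerate, a2, d2), 0.0))
    dmin = _dmin_for_pairs(iu, ju, repar, table)
    ov = np.maximum(dmin - d_interp, 0.0)

    O = np.zeros((m, m))
    O[iu, ju] = ov
    O[ju, iu] = ov
    D = np.zeros((m, m))
    D[iu, ju] = d_interp
    D[ju, iu] = d_interp

    local_mask = (ju - iu) <= LOCAL_SEPARATION
    local = float(ov[local_mask].sum())
    nonlocal_ = float(ov[~local_mask].sum())
    mean = float(ov.sum() / m)
    return OverlapResult(
        overlap_matrix=O,
        d_interp_matrix=D,
        mean_overlap=mean,
        local_overlap=local,
        nonlocal_overlap=nonlocal_,
        table=tuple(table),
        representation=morph.representation,
    )


def _segment_lengths(morph: Morph, seg: int):
    """Lengths of segment ``seg`` (0-based) in both end structures."""
    return (
        float(np.linalg.norm(morph.curve0[seg + 1] - morph.curve0[seg])),
        float(np.linalg.norm(morph.curve1[seg + 1] - morph.curve1[seg])),
    )


def needs_intersection_check(
    i: int,
    j: int,
    overlaps: OverlapResult,
    morph: Morph,
    representation: Optional[str] = None,
) -> bool:
    """Whether segments i and j (0-based, non-adjacent) need the full
    self-intersection check.

    The check may be skipped only if all four involved neighbor spacings (the
    two segments' lengths in both end structures) are below the spacing bound
    and the 4-term endpoint overlap sum is below the overlap bound.  Segment
    lengths during the morph are convex in t, so the endpoint bound holds for
    all t.
    """
    rep = representation or morph.representation
    spacing_max, overlap_max = SKIP_THRESHOLDS[rep]
    lens = _segment_lengths(morph, i) + _segment_lengths(morph, j)
    if any(L >= spacing_max for L in lens):
        return True
    O = overlaps.overlap_matrix
    s = O[i, j] + O[i, j + 1] + O[i + 1, j] + O[i + 1, j + 1]
    return bool(s >= overlap_max)
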