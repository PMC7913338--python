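"""Rigid superposition, the global one-gap RMSD alignment, and alignment scores.

The three scores (RMSD, GDT-TS, TM) are computed from the per-residue
displacement distances d_i of n aligned, superimposed residue pairs:

    RMSD   = sqrt(mean d_i^2)
    GDT-TS = mean over m in {1,2,4,8} A of the fraction of residues with d_i <= m
    TM     = (1/n) sum 1 / (1 + (d_i/d0)^2),  d0 = 1.24 (n-15)^(1/3) - 1.8

TM is normalized by the common morph length n (single-length convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .chain_io import AlignmentRecord, Chain

__all__ = [
    "ScoreSet",
    "kabsch_superpose",
    "global_rmsd_align",
    "alignment_scores",
    "tm_d0",
]

GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)


@dataclass
class ScoreSet:
    rmsd: float
    gdt_ts: float
    tm: Optional[float]
    d0: Optional[float]
    n: int
    per_residue_distances: np.ndarray = field(
        default_factory=lambda: np.zeros(0)
    )


def tm_d0(n: int) -> float:
    """TM-score distance scale d0 = 1.24 (n-15)^(1/3) - 1.8 (Å)."""
    if n <= 15:
        raise ValueError(f"d0 undefined for n={n} (needs n > 15)")
    d0 = 1.24 * (n - 15) ** (1.0 / 3.0) - 1.8
    if d0 <= 0:
        raise ValueError(f"d0 non-positive for n={n}")
    return d0


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Proper rotation R and translation t minimizing RMSD of ``Y`` onto ``X``.

    Returns (R, t, rmsd) with det(R) = +1 so mirror images are never matched
    by a reflection.  The transform maps y -> R @ y + t.
    """
    X = np.asarray(X, dtype=float).reshape(-1, 3)
    Y = np.asarray(Y, dtype=float).reshape(-1, 3)
    if len(X) != len(Y):
        raise ValueError("point lists must have equal length")
    if len(X) < 3:
        raise ValueError("at least 3 points required")
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    H = (Y - cy).T @ (X - cx)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cx - R @ cy
    moved = Y @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - X) ** 2, axis=1))))
    return R, t, rmsd


def global_rmsd_align(
    chain0: Chain,
    chain1: Chain,
    max_length_ratio: float = 0.10,
    allow_ratio_override: bool = False,
) -> AlignmentRecord:
    """Align the entire shorter chain with minimal RMSD allowing one inner gap.

    All placements of a single gap (of the fixed length ``|n0 - n1|``) in the
    shorter chain are enumerated exhaustively, including the terminal
    placements which reduce to a gapless offset alignment; each placement is
    superimposed by Kabsch and the minimum-RMSD placement is returned.
    """
    n0, n1 = len(chain0), len(chain1)
    short_first = n0 <= n1
    ns, nl = (n0, n1) if short_first else (n1, n0)
    if nl > ns * (1.0 + max_length_ratio) and not allow_ratio_override:
        raise ValueError(
            f"length ratio {nl / ns:.3f} exceeds 1 + {max_length_ratio}; "
            "pass allow_ratio_override=True to force"
        )
    gap = nl - ns
    Ps = chain0.points if short_first else chain1.points
    Pl = chain1.points if short_first else chain0.points

    best = None
    for g in range(ns + 1):  # gap after shorter-chain position g (0/ns = terminal)
        long_idx = np.concatenate(
            [np.arange(0, g), np.arange(g + gap, ns + gap)]
        )
        R, t, rmsd = kabsch_superpose(Ps, Pl[long_idx])
        if best is None or rmsd < best[0] - 1e-12:
            best = (rmsd, g, long_idx, R, t)
    rmsd, g, long_idx, R, t = best

    if short_first:
        pairs = [(i + 1, int(j) + 1) for i, j in enumerate(long_idx)]
        # transform maps chain1 (the longer) onto chain0
        rotation, translation = R, t
        len0, len1 = n0, n1
    else:
        pairs = [(int(j) + 1, i + 1) for i, j in enumerate(long_idx)]
        # Kabsch mapped the longer (= chain0) onto the shorter (= chain1);
        # invert so the stored transform moves chain1 onto chain0.
        rotation = R.T
        translation = -R.T @ t
        len0, len1 = n0, n1
    return AlignmentRecord(
        pairs=pairs,
        weak_flags=[False] * len(pairs),
        len0=len0,
        len1=len1,
        rotation=rotation,
        translation=translation,
        method="global_rmsd",
    )


def alignment_scores(d, n: Optional[int] = None) -> ScoreSet:
    """Score a displacement-distance list with RMSD, GDT-TS and TM.

    ``n`` defaults to ``len(d)``.  For n <= 15 the TM d0 scale is undefined;
    RMSD and GDT-TS are still returned and ``tm``/``d0`` are None.
    """
    d = np.asarray(d, dtype=float).ravel()
    if n is None:
        n = len(d)
    if len(d) != n:
        raise ValueError("d must have n entries")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    rmsd = float(np.sqrt(np.mean(d**2)))
    gdt = float(np.mean([(d <= m).mean() for m in GDT_THRESHOLDS]))
    try:
        d0 = tm_d0(n)
        tm = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
    except ValueError:
        warnings.warn(f"TM-score undefined for n={n} (<= 15)", stacklevel=2)
        d0 = None
        tm = None
    return ScoreSet(
        rmsd=rmsd, gdt_ts=gdt, tm=tm, d0=d0, n=int(n), per_residue_distances=d
    )
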