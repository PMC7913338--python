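"""Full analysis of one aligned, superimposed chain pair.

The stages run in the order the method is defined: rigid transform,
optional smoothening, gap reparameterization, overlap, filtered
self-intersection detection, Ω1/Ω2 candidate construction, the essential-set
matching, optional end-contractions, and the morph-length decomposition

    total = L1 + move prices + thickness penalties + end-contraction cost
            + torsion_weight * |signed Ω1 sign sum| + overlap_weight * MeanOverlap,

where L1 = sum_i |p1_i - p0_i| over the reparameterized vertices and the
thickness penalty per move is pi*d/2 times the number of vertices the move
rearranges (d = 3.7 Å, the overlap-free tube diameter: each rearranged point
traverses half a circle of radius d/2 to swap over- and under-sliding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .chain_io import AlignmentRecord, Chain
from .endcontract import optimize_end_contractions, terminal_omega1_price
from .essential import EssentialResult, build_move_graph, solve_essential
from .intersect import Diagnostics, SelfIntersection, find_intersections
from .morphgeo import Morph, smooth_chain
from .moves import MoveCandidate, omega1_candidate, omega2_candidate
from .overlap import OverlapResult, overlap_analysis
from .reparam import (
    ReparamPair,
    build_reparam,
    classify_intersection_alignment,
    eval_curve,
)
from .superpose import ScoreSet, alignment_scores, global_rmsd_align

__all__ = ["Config", "MorphReport", "analyze_pair", "morph_length", "build_morph"]

THICKNESS_D = 3.7  # Å, shortest overlap-free distance


@dataclass
class Config:
    """User-facing knobs of the analysis.

    max_length is the maximal backbone span (in residues/segments) a single
    Ω move may rearrange; end_contraction_limit defaults to half of it.
    The torsion and overlap weights default to 0 so the total matches the
    primary morph-length definition.
    """

    max_length: float = 10.0
    representation: str = "alpha"  # "alpha" | "smooth"
    allow_end_contractions: bool = False
    end_contraction_limit: Optional[float] = None
    end_proximal_omega1: bool = False
    torsion_penalty_weight: float = 0.0
    overlap_weight: float = 0.0
    use_cost_estimates: bool = False
    solver: str = "optimal"  # "optimal" | "greedy"
    use_overlap_filter: bool = True

    def __post_init__(self):
        if self.max_length < 0:
            raise ValueError("max_length must be >= 0")
        if self.torsion_penalty_weight < 0 or self.overlap_weight < 0:
            raise ValueError("weights must be >= 0")
        if self.end_contraction_limit is None:
            self.end_contraction_limit = self.max_length / 2.0


@dataclass
class MorphReport:
    overlap: OverlapResult
    intersections: List[SelfIntersection]
    candidates: List[MoveCandidate]
    essential_result: EssentialResult
    end_contractions: list
    end_contraction_window: Optional[Tuple[float, float]]
    end_contraction_cost: float
    resolved_by_contraction: bool
    l1_length: float
    move_price_total: float
    thickness_penalty: float
    torsion_effect: float
    total_morph_length: float
    scores: ScoreSet
    awf: float
    self_avoiding: bool
    diagnostics: Diagnostics


def build_morph(
    chain0: Chain,
    chain1: Chain,
    alignment: AlignmentRecord,
    representation: str = "alpha",
) -> Tuple[Morph, ReparamPair]:
    """Apply the alignment transform, optional smoothening and the gap
    reparameterization; returns the morph and the reparameterization."""
    moved1 = Chain(
        points=alignment.transform_points(chain1.points),
        residue_labels=list(chain1.residue_labels),
        representation=chain1.representation,
        source_id=chain1.source_id,
    )
    c0, c1 = chain0, moved1
    if representation == "smooth":
        c0 = smooth_chain(c0)
        c1 = smooth_chain(c1)
    rp = build_reparam(alignment)
    curve0 = eval_curve(c0, rp.repar0)
    curve1 = eval_curve(c1, rp.repar1)
    morph = Morph(
        curve0=curve0,
        curve1=curve1,
        representation=representation,
        provenance=alignment.method,
    )
    return morph, rp


def _thickness_penalty(cand: MoveCandidate) -> float:
    half_circ = math.pi * THICKNESS_D / 2.0
    if cand.kind == "omega1":
        return half_circ * abs(cand.backbone_length + 1.0)
    return half_circ * abs(cand.backbone_length + 2.0)


def analyze_pair(
    chain0: Chain,
    chain1: Chain,
    alignment: Optional[AlignmentRecord] = None,
    config: Config = None,
) -> MorphReport:
    """Run the complete obstruction analysis for one chain pair.

    With ``alignment=None`` the global one-gap minimal-RMSD alignment is
    computed first.  Errors from individual stages propagate with a stage
    label prefixed.
    """
    cfg = config if config is not None else Config()
    if alignment is None:
        alignment = global_rmsd_align(chain0, chain1)

    stage = "reparameterization"
    try:
        morph, rp = build_morph(
            chain0, chain1, alignment, representation=cfg.representation
        )
        stage = "overlap"
        overlaps = overlap_analysis(morph, repar=rp)
        stage = "intersection detection"
        diag = Diagnostics()
        intersections = find_intersections(
            morph, overlaps if cfg.use_overlap_filter else None, diagnostics=diag
        )
        for si in intersections:
            si.alignment_class = classify_intersection_alignment(si, rp)

        stage = "move candidates"
        omega1s = [
            omega1_candidate(si, morph, cfg.max_length) for si in intersections
        ]
        if cfg.end_proximal_omega1:
            omega1s = [
                terminal_omega1_price(
                    si, morph, cand, cfg.max_length,
                    use_estimates=cfg.use_cost_estimates,
                )
                for si, cand in zip(intersections, omega1s)
            ]
        omega2s = []
        for x in range(len(intersections)):
            for y in range(x + 1, len(intersections)):
                si_x, si_y = intersections[x], intersections[y]
                if si_x.sign + si_y.sign != 0:
                    continue
                combined = (si_x.b - si_x.a) + (si_y.b - si_y.a)
                if combined > cfg.max_length:
                    continue
                omega2s.append(omega2_candidate(si_x, si_y, morph, cfg.max_length))

        stage = "essential set"
        graph = build_move_graph(intersections, omega1s, omega2s)
        result = solve_essential(graph, method=cfg.solver)

        stage = "end-contractions"
        contractions: list = []
        window = None
        contraction_cost = 0.0
        resolved = False
        if result.N > 0 and cfg.allow_end_contractions:
            ess = [intersections[k] for k in result.essential]
            best = optimize_end_contractions(
                ess,
                morph,
                limit=cfg.end_contraction_limit,
                use_estimates=cfg.use_cost_estimates,
            )
            if best is not None:
                a, b, contraction_cost, contractions = best
                window = (a, b)
                resolved = True

        stage = "morph length"
        l1 = float(
            np.linalg.norm(morph.curve1 - morph.curve0, axis=1).sum()
        )
        used: List[MoveCandidate] = []
        by_member = {c.members[0]: c for c in omega1s}
        for k in result.omega1_used:
            used.append(by_member[k])
        edge_cands = {tuple(sorted(c.members)): c for c in omega2s if c.feasible}
        for e in result.matching:
            used.append(edge_cands[tuple(sorted(e))])
        thickness = sum(_thickness_penalty(c) for c in used)
        torsion = abs(
            sum(by_member[k].writhe_jump // 2 for k in result.omega1_used)
        )
        d_vertices = np.linalg.norm(morph.curve1 - morph.curve0, axis=1)
        scores = alignment_scores(d_vertices)
        total = (
            l1
            + result.total_price
            + thickness
            + contraction_cost
            + cfg.torsion_penalty_weight * torsion
            + cfg.overlap_weight * overlaps.mean_overlap
        )
        self_avoiding = result.N == 0 or resolved
        return MorphReport(
            overlap=overlaps,
            intersections=intersections,
            candidates=omega1s + omega2s,
            essential_result=result,
            end_contractions=contractions,
            end_contraction_window=window,
            end_contraction_cost=float(contraction_cost),
            resolved_by_contraction=resolved,
            l1_length=l1,
            move_price_total=float(result.total_price),
            thickness_penalty=float(thickness),
            torsion_effect=float(torsion),
            total_morph_length=float(total),
            scores=scores,
            awf=rp.awf,
            self_avoiding=self_avoiding,
            diagnostics=diag,
        )
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def morph_length(report: MorphReport, config: Config = None) -> Dict[str, float]:
    """Re-assemble the morph-length decomposition from a report.

    Returns the components and their sum; the sum equals
    ``report.total_morph_length``.
    """
    cfg = config if config is not None else Config()
    components = {
        "l1_length": report.l1_length,
        "move_price_total": report.move_price_total,
        "thickness_penalty": report.thickness_penalty,
        "end_contraction_cost": report.end_contraction_cost,
        "torsion_term": cfg.torsion_penalty_weight * report.torsion_effect,
        "overlap_term": cfg.overlap_weight * report.overlap.mean_overlap,
    }
    components["total"] = float(sum(components.values()))
    return components
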