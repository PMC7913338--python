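"""Minimal essential set via one maximum-weight matching.

Vertices are self-intersections; an edge is a feasible Ω2 pair.  With
epsilon = 1 / (2 * sum of all feasible move prices), vertex weights

    w_v(v) = eps * P1(v)  if v is Ω1-removable, else 1,

and edge weights w(e) = w_v(v_i) + w_v(v_j) - eps * P2(v_i, v_j), every
matching E' satisfies the identity

    N(E') + eps * P(E') = K + eps * P1_all - sum_{e in E'} w(e),

where K counts non-Ω1 vertices and P1_all sums the Ω1 prices.  Since
0 <= eps * P(E') <= 1/2, a maximum-weight matching minimizes the number of
remaining (essential) intersections first and the total move price second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .intersect import SelfIntersection
from .moves import MoveCandidate

__all__ = ["MoveGraph", "EssentialResult", "build_move_graph", "solve_essential"]


@dataclass
class MoveGraph:
    vertices: List[int]  # intersection indices k
    vertex_weights: Dict[int, float]
    omega1_feasible: Dict[int, bool]
    omega1_price: Dict[int, float]
    edges: List[Tuple[int, int]]
    edge_weights: Dict[Tuple[int, int], float]
    edge_price: Dict[Tuple[int, int], float]
    edge_length: Dict[Tuple[int, int], float]
    epsilon: float
    K: int  # vertices not Ω1-feasible
    p1_all: float  # sum of Ω1 prices over feasible vertices


@dataclass
class EssentialResult:
    matching: List[Tuple[int, int]]  # Ω2 edges used
    omega1_used: List[int]
    essential: List[int]
    N: int
    total_price: float
    objective: float  # A(E*) = N + eps * P


def build_move_graph(
    intersections: Sequence[SelfIntersection],
    omega1_results: Sequence[MoveCandidate],
    omega2_results: Sequence[MoveCandidate],
) -> MoveGraph:
    """Assemble the weighted matching instance from move candidates.

    Infeasible candidates contribute nothing.  When no move is feasible the
    total price is 0 and epsilon is defined as 0 (all weights integral).
    """
    vertices = [si.k for si in intersections]
    o1 = {c.members[0]: c for c in omega1_results if c.kind == "omega1"}
    feasible1 = {k: (k in o1 and o1[k].feasible) for k in vertices}
    price1 = {k: (o1[k].price if feasible1[k] else 0.0) for k in vertices}

    feasible2 = [c for c in omega2_results if c.kind == "omega2" and c.feasible]
    total_price = sum(price1.values()) + sum(c.price for c in feasible2)
    eps = 0.0 if total_price <= 0 else 1.0 / (2.0 * total_price)

    w_v = {k: (eps * price1[k] if feasible1[k] else 1.0) for k in vertices}
    edges, e_w, e_p, e_len = [], {}, {}, {}
    for c in feasible2:
        u, v = sorted(c.members)
        key = (u, v)
        if key in e_w and e_w[key] >= w_v[u] + w_v[v] - eps * c.price:
            continue  # keep the best parallel edge
        if key not in e_w:
            edges.append(key)
        e_w[key] = w_v[u] + w_v[v] - eps * c.price
        e_p[key] = c.price
        e_len[key] = c.backbone_length

    K = sum(1 for k in vertices if not feasible1[k])
    p1_all = sum(price1[k] for k in vertices if feasible1[k])
    return MoveGraph(
        vertices=vertices,
        vertex_weights=w_v,
        omega1_feasible=feasible1,
        omega1_price=price1,
        edges=edges,
        edge_weights=e_w,
        edge_price=e_p,
        edge_length=e_len,
        epsilon=eps,
        K=K,
        p1_all=p1_all,
    )


def matching_objective(graph: MoveGraph, matching: Sequence[Tuple[int, int]]):
    """(N, P, A) for an arbitrary matching E': vertices not matched and not
    Ω1-feasible remain essential; remaining Ω1-feasible vertices are removed
    by their Ω1 moves."""
    matched = set()
    for (u, v) in matching:
        if u in matched or v in matched:
            raise ValueError("not a matching: vertex reused")
        matched.update((u, v))
    omega1_used = [
        k for k in graph.vertices if k not in matched and graph.omega1_feasible[k]
    ]
    essential = [
        k for k in graph.vertices if k not in matched and not graph.omega1_feasible[k]
    ]
    price = sum(graph.edge_price[tuple(sorted(e))] for e in matching) + sum(
        graph.omega1_price[k] for k in omega1_used
    )
    N = len(essential)
    A = N + graph.epsilon * price
    return N, price, A, omega1_used, essential


def solve_essential(graph: MoveGraph, method: str = "optimal") -> EssentialResult:
    """Select Ω2 moves (a matching) and Ω1 moves minimizing the essential
    count N, then the total price.

    ``optimal`` uses an exact maximum-weight matching on a general graph
    (Blossom-class); ``greedy`` scans Ω2 candidates by increasing backbone
    length and accepts any pair whose vertices are both unused, which is
    faster but can leave more essential intersections.
    """
    if method == "optimal":
        G = nx.Graph()
        G.add_nodes_from(graph.vertices)
        for e in graph.edges:
            # deterministic 1e-12-scale perturbation prefers shorter loops on
            # ties; cannot change N or the price beyond numerical noise
            tie = 1e-12 * (graph.edge_length[e] + 1e-3 * e[0])
            G.add_edge(*e, weight=graph.edge_weights[e] - tie)
        raw = nx.max_weight_matching(G, maxcardinality=False, weight="weight")
        matching = sorted(tuple(sorted(e)) for e in raw)
    elif method == "greedy":
        used = set()
        matching = []
        order = sorted(
            graph.edges, key=lambda e: (graph.edge_length[e], e)
        )
        for (u, v) in order:
            if u in used or v in used:
                continue
            used.update((u, v))
            matching.append((u, v))
    else:
        raise ValueError(f"unknown method {method!r}")

    N, price, A, omega1_used, essential = matching_objective(graph, matching)
    return EssentialResult(
        matching=matching,
        omega1_used=sorted(omega1_used),
        essential=sorted(essential),
        N=N,
        total_price=price,
        objective=A,
    )
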