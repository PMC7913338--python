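# Methods

## Model

Two protein chains are reduced to their alpha-carbon traces
P⁰ = [p⁰₁ … p⁰ₙ], P¹ = [p¹₁ … p¹ₙ], assumed (or brought) into rigid
superposition.  The object of study is the linear morph
P(t, a) = (1 − t) P⁰(a) + t P¹(a) with time t ∈ [0, 1] and curve parameter
a ∈ [1, m], where P(·) between integer parameters is the piecewise-linear
interpolation of the trace.  The analysis asks two questions about this
morph: how much it violates native packing distances (overlap), and whether
it changes the embedding class of the curve within a user-set neighborhood
(essential self-intersections).

### Overlap

For vertices i < j write a = |p⁰ⱼ − p⁰ᵢ|, b = |p¹ⱼ − p¹ᵢ| and
ab·cosθ = p⁰ᵢⱼ·p¹ᵢⱼ.  Then d²ᵢⱼ(t) is quadratic in t with unconstrained
minimizer t* = (a² − ab·cosθ)/(a² + b² − 2ab·cosθ), clamped to [0, 1]; when
the relative vector is constant the distance is constant and t* is
undefined (we fix the clamp at 0; the distance value is what matters).
The native minimum CA–CA distances are 2.8, 4.5, 3.86, 3.47, 3.52, 3.48,
3.6 Å for separations 1…7 and 3.7 Å beyond; the first entry is deliberately
small because helices legitimately compress neighbor distances during
interpolation.  Smoothened curves use 1.0, 2.1, 3.0, 3.4, 3.6 Å for
separations 1…5, then 3.7 Å.  Overlap is penalized linearly,
overlapᵢⱼ = max(d_min − d_interp, 0), and MeanOverlap divides the sum by the
vertex count.  The local/nonlocal split is at |i − j| ≤ 4.

For reparameterized (gapped) morphs a vertex pair has two backbone
separations, one per original curve.  We apply the **weaker** of the two
constraints, d_min(i, j) = min(d_min(sep⁰), d_min(sep¹)): if either backbone
places the pair close in sequence, that proximity is legitimate and should
not be scored as a clash.  For ungapped morphs both separations coincide and
the rule reduces to the plain table.

### Self-intersection detection

Segments i and j (non-adjacent, |i − j| ≥ 2; adjacent pairs share a vertex
and are coplanar-degenerate) can pass through each other only at roots of
the cubic det(P_{i+1}−P_i, P_{j+1}−P_j, P_i−P_j)(t).  The cubic's
coefficients are recovered exactly from evaluations at t = 0, ⅓, ⅔, 1;
roots come from the companion-matrix solver and are Newton-polished on the
max-normalized polynomial (tolerance 1e-9).  At each real root in [0, 1]
the coplanar 2-unknown system for (s_i, s_j) is solved by least squares
(the 3×2 system is consistent at a true root; a residual above 1e-5 of the
coordinate scale marks coplanar-but-disjoint lines) and the event is kept
iff s_i, s_j ∈ [0, 1] with 1e-9 slack.  The crossing-sign change is the
sign of the cubic's derivative at the root; roots with derivative below
tolerance are tangential, not transversal, and are discarded but counted in
the diagnostics.  Roots within tolerance of t = 0 or 1 are kept and flagged
`boundary` — transversality at the morph endpoints is genuinely ambiguous
and left to the caller.

Checks are skipped when they provably cannot fire: segment lengths during
the morph are convex in t, so if both segments are shorter than 4 Å in both
end structures (3.5 Å for smooth curves) and the four endpoint overlaps sum
below 2.6 Å (2.1 Å smooth), the spheres carried by the endpoints never
admit a crossing.  We require the spacing bound in **both** structures — the
conservative reading — so the filter can only skip pairs that cannot
intersect; filtered and unfiltered detection are asserted equal in the
tests.

### Ω moves and prices

An intersection (a, b, sign, t*) is locally Ω1-removable when b − a ≤
MaxLength and the triangle fan from the loop P_a(t*), P_⌈a⌉(t*), …,
P_⌊b⌋(t*), P_b(t*) to its center of mass is disjoint from the remainder of
the t*-slice (segments fully upstream of a or downstream of b; the partial
pieces adjoining the loop belong to the loop).  The price 𝒫1 is twice the
summed distances of the loop points to the line through the intersection
point and the centroid — the axis about which the loop is rotated to the
other side.  The free-disk scan translates the centroid to the origin,
sorts segments by midpoint distance, and stops once
midpoint distance − (suffix-max half-length) exceeds the maximal boundary
radius, which is a sound triangle-inequality cut.

Two opposite-sign intersections form an Ω2 candidate when their combined
backbone span is within MaxLength.  At t_avg = (t*_j + t*_k)/2 the disk over
the two connecting arcs (the a-arc and the reversed b-arc, closed by the
two short chords near the events) must be free, and the tracks swept by the
two intersection points over [t*_j, t*_k] — re-solved at 64 uniform times
as the midpoint of the closest-point pair of the two segments and joined
into polylines — must keep more than 1e-6 Å from the remainder of the
moving curve at matching times.  We test the tracks separately rather than
triangulating them into the disk; pairs whose arcs interleave along the
backbone are rejected as candidates.  The price 𝒫2 is twice the summed
distances of the loop points to the line connecting the two a-arc
endpoints at t_avg.

Each Ω1 move carries a ±2 writhe jump; the net |Σ sign| over the Ω1 moves
used is reported as the torsion effect, with weight 0 by default.

### Essential set

With ε = 1/(2·Σ all feasible move prices) (ε = 0 when no move is feasible),
vertex weights w_v = ε𝒫1 for Ω1-removable intersections and 1 otherwise,
and edge weights w(e) = w_v(vᵢ) + w_v(vⱼ) − ε𝒫2, every matching E′
satisfies N(E′) + ε𝒫(E′) = K + ε𝒫1_all − Σ_{e∈E′} w(e) — an identity the
test suite checks on random matchings, not only the optimum.  Because
0 ≤ ε𝒫 ≤ ½, a maximum-weight matching (networkx's exact Blossom-class
solver) minimizes the essential count N first and the price second.  Edge
weights receive a deterministic 1e-12-scale perturbation preferring shorter
loops, which fixes tie membership without affecting N; following the
method's own advice, only N should be emphasized, since near-ties in prices
can flip which intersections are labeled essential.  The greedy variant
scans feasible Ω2 candidates by increasing backbone length (ties by vertex
index) and can strand vertices an optimal matching would save.

### End-contractions

An N-contraction moves all points upstream of P_a to P_a in both end
structures; its cost is the travel in both structures plus
m = ⌊a⌋ times the displacement of P_a under the original morph (the
contracted points ride along).  The path is shortened greedily: P_m always
moves straight (it slides along its own segment); each further upstream
point takes the straight shortcut to the current obstruction point if the
triangle (head, P_{r+1}, P_r) is disjoint from the curve at parameters ≥ a,
otherwise a new obstruction point inside the triangle is chosen from a
15×15 barycentric grid plus points offset 0.5 Å from each blocking
piercing toward the head, minimizing the two-leg length subject to > 1e-6 Å
clearance; if no candidate clears, the path falls back to routing via
P_{r+1} along the backbone.  There is no backtracking.  C-contractions
mirror this exactly on the reversed chain.

The combined optimum over N- and C-contractions removing every essential
intersection is restricted, without loss, to the n + 1 candidates a = a_j,
b = min(b_{j+1}, …, bₙ, L): the N-cost is monotone in a and the C-cost
antitone in b, so each constraint pattern attains its optimum at one of
these pairs (verified against a dense (a, b) grid in the tests).  The
estimator replaces exact paths by the empirical ramp d(r) = 25·r/17 Å for
r ≤ 17 and 25 Å beyond, summed over contracted residues, doubled for the
two structures, plus the same m·displacement term.  An intersection within
MaxLength/2 of a terminus may optionally be treated as Ω1-removable at the
cheaper of its Ω1 price and its single-end contraction cost.

### Morph length

total = L1 + Σ move prices + π·d/2 · (span + 1 or span + 2) per Ω1/Ω2 move
(d = 3.7 Å: swapping over- for under-sliding forces each rearranged vertex
around half a tube circumference) + end-contraction cost + weight·torsion +
weight·MeanOverlap.  Both optional weights default to 0 so the default
total is the primary definition.

### Alignments and reparameterization

TM-align blocks are parsed from the standard three-line alignment (":"
aligned, "." weakly aligned — treated as aligned but flagged — and gaps);
the global alignment is an exhaustive search over all placements of one
inner gap of the fixed length |n₀ − n₁| aligning the entire shorter chain,
each placement superimposed by Kabsch (proper rotations only).  Between
consecutive aligned pairs spanning g0 and g1 intervals, max(g0, g1) uniform
steps are inserted so both curves arrive simultaneously; inserted vertices
get IsAligned = 0 and intersections are classified by
AlignedSum = IsAligned(a) + IsAligned(b) at thresholds ≥ 1.5 / > 0.5.
Unaligned terminal overhangs are excluded from the morph.  The d_min table
is interpolated linearly at fractional separations and held constant beyond
its last entry (so separations in (7, 8) interpolate 3.6 → 3.7 Å).
Scores: GDT-TS uses non-strict ≤ at its 1, 2, 4, 8 Å cuts; TM normalizes by
the common morph length with d₀ = 1.24(n−15)^⅓ − 1.8, undefined (returned
as None, with RMSD and GDT-TS still computed) for n ≤ 15.

## Synthetic data

The generators construct, in closed form, the geometric situations the
method is about, embedded in clash-free scaffolds (all fixtures have zero
overlap at both morph endpoints, and the interpolation from each fixture
chain to its smoothened curve is self-intersection free):

- `make_crossing_change_pair(n)` — the motivating construction: identical
  serpentine chains (3.8 Å spacing, 15.2 Å lane separation) except that a
  central over/under crossing (heights 0, 0, 1.25, 2.5, 2.5, 1.25, 0, 0 Å
  against the negated profile) is interchanged, so exactly 4 residues move
  5 Å and 4 move 2.5 Å and the morph has exactly one transversal
  self-intersection at t* = ½.  The minimal core (two 8-point strands plus
  an 8-point connector) sets the minimum n at 24.
- `make_loop_fixtures(kind)` — `removable_loop`: mirrored-handedness loops
  (11-point arc of radius 7 Å, fine enough that smoothening barely moves
  it) giving one Ω1-feasible intersection; `threaded_loop`: the same with a
  static strand through the spanning disk (Ω1-infeasible, blocker
  reported); `slide_pair`: a V-shaped strand slid across a straight one,
  two opposite-sign intersections at the same t*, Ω2-feasible.

These fixtures emulate topology and packing, not protein energetics,
persistence length or realistic secondary structure; passing tests
demonstrate the geometric and combinatorial machinery, not performance on
experimental coordinates.  Real chains are consumed through the PDB reader
(CA records only, alternate locations by highest occupancy, missing CAs
exposed as label gaps with policy left to the caller).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_length` | 10 residues | largest backbone span one Ω move may rearrange |
| `representation` | alpha | alpha-carbon trace or 5-point smoothed curve (weights 1, 2.4, 2.1, 2.4, 1 / 8.9, chosen to minimize total curvature; ends fixed) |
| `allow_end_contractions` | off | resolve remaining essentials by terminus contraction |
| `end_contraction_limit` | max_length/2 | most residues a contraction may involve |
| `use_cost_estimates` | off | ramp estimator instead of exact contraction paths |
| `solver` | optimal | exact matching vs greedy scan |
| `torsion_penalty_weight`, `overlap_weight` | 0 | optional morph-length terms |

## Numerical choices and limitations

Root tolerance 1e-9 on the normalized cubic; containment slack 1e-9;
track/path clearance 1e-6 Å; 64 track samples; 15×15 barycentric grid.
Problem sizes in the tests (n = 100 pairs, 12–16-vertex random morphs, 200
sampling-oracle morphs, 500 disk instances, 50 matching instances) were
chosen so each suite probes its claim at full strength while the whole run
stays interactive.

Known limitations: Ω3 moves and multi-pass disk deformations around
blockers are out of scope, so an intersection can be labeled essential that
a cleverer (non-local) rearrangement could avoid — the label is geometric
("no fix within this neighborhood of the morph"), not topological.  The
end-contraction path is greedy and one-pass, an upper bound on the shortest
contraction; the morph length is a crude upper estimate of the shortest
self-avoiding morph.  Exactly coincident t* values are ordered by (t*, a,
b); Ω2 pairing is unaffected.  When two curves stay coplanar over an
interval the determinant vanishes identically and no transversal event is
reported.
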