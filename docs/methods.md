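# Methods

## Model

A landscape is an attributed directed graph `G(N, A)`. Habitat patches
(wetlands) and intervening land-cover areas are nodes with planar
coordinates (projected meters; no geodesy), elevation, and optionally a
topographic wetness index (TWI) value. Adjacencies between neighboring
areas are stored as **two** directed arcs because elevation cost is
direction-dependent; symmetric raw attributes (length, land cover,
moisture) are shared by both directions. At most one arc exists per ordered
node pair.

A corridor between habitats `o` and `d` is a path satisfying conservation
of flow. Three additive, nonnegative objectives are minimized
simultaneously:

1. **Traversal-failure risk.** Each arc has a failure probability
   `π_ij ∈ [0, 1)`; a path fails with probability `1 − Π(1 − π_ij)`. The
   product form is neither linear nor additive, so internally the risk is
   carried as `f₁ = Σ ln(1/(1 − π_ij))`, which is additive, monotone, and
   order-isomorphic to the probability (`Ω₁ = 1 − exp(−f₁)`). All dominance
   comparisons use the log form; the probability is a reporting view.
2. **Moisture-weighted distance.** `f₂ = Σ (M − m_ij + 1) c_ij`: arc length
   `c_ij` scaled up the further arc moisture `m_ij` (TWI units) falls below
   an ideal level `M`.
3. **Elevation cost.** `f₃ = Σ z_ij` with
   `z_ij = w_p (e_j − e_i)` uphill, `w_n (e_i − e_j)` downhill.

Additivity and monotonicity of all three give the Bellman subpath property
(every prefix of an efficient path is efficient to its intermediate node),
which is the correctness condition for both solution algorithms.

Arcs with both endpoints in the same wetland carry `(0, 0, 0)`: habitat
interiors are treated as homogeneous, and movement within them is free.
This introduces zero-cost cycles that the algorithms must tolerate.

## Cost derivation parameters

| parameter | default | units | notes |
|---|---|---|---|
| `w_p` (uphill weight) | 2.0 | – | uphill assumed twice as costly as downhill; only the `w_p:w_n` ratio affects the Pareto set |
| `w_n` (downhill weight) | 1.0 | – | |
| `ideal_moisture` `M` | max observed arc TWI | TWI | keeps every moisture deviation ≥ 0; configurable when a species-specific ideal is known |
| moisture offset | 1.0 | TWI | the `+1` keeping nonzero-length arcs strictly positive in `f₂` |
| base risk `π_b` per land-cover class | 0.060–0.095 | probability | woody wetland 0.060, deciduous forest 0.065, deciduous woody 0.070, grassland 0.075, open water 0.085, cropland 0.090, impervious 0.095 |
| risk length factor | 0.5 | – | `π_ij = π_b (1 + c_ij / (2 c_max))`: up to +50% for the longest arc `c_max` (computed excluding zero-length and wetland-internal arcs) |
| `twi_max`, `twi_min` | site-specific | TWI | substitutes for degenerate cells: zero slope with drainage → max; zero slope and no drainage → min |

TWI is `ln(α / tan β)` (drainage area over slope tangent); raster
flow-accumulation is out of scope — TWI inputs or node moisture are taken
as given, and arc moisture defaults to the mean of its endpoint values
(a midpoint rule would be equally defensible; the choice only shifts `f₂`
smoothly and is configurable by supplying arc moisture directly).

## Scalar solver

The weighted problem `min w·(f₁, f₂, f₃)` is solved as a nonnegative-cost
shortest-path search (Dijkstra), not an LP: the path polytope is integral,
so the relaxation solves the binary problem exactly. Determinism matters
(anchor sets must be reproducible), so ties in the scalar cost are broken
lexicographically by a configurable objective order, then by node sequence.
All key components are additive and nonnegative, so label-setting over the
composite key is exact. Zero-cost cycles are harmless: finalized nodes are
never re-expanded.

**Anchors.** The efficient solution minimal in one objective is classically
obtained with weights like `(1 − 2δ, δ, δ)`, `δ = 10⁻⁴`. That device is not
scale-invariant: when one objective is orders of magnitude larger (here
`f₂` is in the thousands while `f₁` is ~0.1), the `δ` share of the large
objective swamps genuine differences in the anchored one, and the "anchor"
stops being coordinate-minimal (observed on seeded fixtures). Anchors are
therefore solved in the `δ → 0` limit: unit weight on the anchored
objective with the lexicographic tie-break ordered to put it first, which
returns an efficient, coordinate-minimal path on any scale. The `δ`
parameter is retained in the interface but does not enter the arithmetic.

## Supported-frontier enumeration (three objectives)

The search walks weight space. Three anchor solves seed the frontier; the
plane through three known frontier points (the Utopia plane), when its
normal is strictly positive, supplies the next weight. A solve that lands
strictly below its generating plane certifies a new supported point, which
is swapped into the plane vertex-by-vertex to spawn three child planes and
weights (FIFO queue; duplicate weights pruned at 10⁻⁹ ∞-norm, duplicate
frontier vectors at 10⁻⁹ relative). The queue emptying ends the recursion.

Two hardening measures:

* **Confirmation sweep.** The plane recursion cannot start when the anchors
  are affinely dependent — e.g. one path minimizes two objectives at once —
  yet further supported extreme points may exist. After the queue empties,
  the lower-envelope facet normals of the found frontier (free-disposal
  hull `conv(Y) + R³₊`, computed with a convex hull over axis-padded
  points) are probed as weights, zero components nudged inward by 10⁻⁶
  relative; any new point triggers a hull recompute. The sweep terminates
  because each round either adds an extreme point or stops, and it stays
  entirely within weighted-sum scalarization.
* **Tolerance pruning.** Elevation costs telescope (an all-uphill route
  costs exactly `w_p (e_d − e_o)` regardless of route), so distinct routes
  can tie mathematically and differ by a few ulp in floating point. An
  anchor can then undercut a true frontier point by ~10⁻¹⁵ and masquerade
  as an extra supported solution. Points dominated within a 10⁻⁹ relative
  band by another found point are pruned from the output.

Unsupported efficient solutions are invisible to every weighted-sum
scalarization by definition; no attempt is made to find them here.

## Biobjective variant

For a chosen pair of objectives, classic dichotomy in objective space: two
anchors, then for each adjacent frontier pair a solve with weights
proportional to the segment normal; recurse on both sub-segments when the
optimum falls below the segment by more than 10⁻⁹ relative (looser drops
supported points, tighter loops on noise). Axis-parallel segment normals
are nudged inward by 10⁻⁴ of the segment scale. The third objective gets
zero weight; the lexicographic tie-break ordered by the pair keeps returned
representatives pair-efficient. At most `2k − 1` scalar solves for `k`
supported points.

## Complete efficient set (label correcting)

Martins-style search over label sets. A label is a 5-tuple: three
accumulated objective values plus predecessor node and predecessor label id
(the origin starts with `(0, 0, 0)` and null references). Nodes whose label
set changed are queued FIFO for reconsideration; extending a node's labels
along an outgoing arc merges candidates into the neighbor's set with a
dominance filter (dominated labels dropped immediately). At fixpoint, every
surviving label at a destination is backtracked through the predecessor
references to reconstruct one efficient path. Results are
queue-order-independent because the fixpoint is the unique non-dominated
set.

Equal-vector labels at a node are deduplicated by default (first found
wins) — this is what guarantees termination around zero-cost wetland
cycles, since a cycle re-derives an existing vector. The alternative
convention, retaining equal-vector paths as distinct corridors, is
available (`keep_equal_vectors=True`); termination is then guaranteed by a
cycle check on the predecessor chain instead. Counts of efficient *paths*
(not vectors) differ between the conventions; all reports use
vector-deduplicated sets unless asked otherwise.

Dominance comparisons in the labeling are exact (no epsilon): along shared
prefixes the compared sums are built from identical addends, so spurious
epsilon-ties would be more common than epsilon-misses.

## Supported/unsupported classification

A frontier point is supported iff some strictly positive weight vector
makes it a minimizer of the weighted sum over the frontier (equivalently it
lies on the lower convex envelope). Points interior to an envelope facet
("weakly supported") are classified supported: the facet weight attains
them, so scalarization can reach them. The test is an LP per point:
maximize the minimum weight component subject to `w·y ≤ w·y′` for all
frontier points and `Σw = 1`; supported iff the optimum exceeds 10⁻⁶. The
threshold sits above the LP solver's feasibility tolerance (a smaller floor
lets zero weights through) and below any weight range that arises for
genuinely supported points in practice; points supported only by weights
below it classify as unsupported.

## Synthetic landscapes

The generator emulates, at reduced scale, the structure of a vector-based
wetland-landscape network: a `grid_n × grid_n` planar grid (spacing 50 m)
with a smooth random elevation field (low-frequency cosine mixture, ~13 m
relief), TWI anticorrelated with elevation plus smooth noise in a
[−0.66, 21.77] band, categorical land cover from thresholded smooth noise
over the seven-class base-risk table, and wetlands as two-node blocks
anchored at the lowest elevations with zero-cost internal arcs and all
members acting as entrance/exit nodes. Grids are connected by construction.
All randomness flows from a single integer seed.

What it does **not** emulate: irregular patch geometry, multi-node wetland
polygons with interior structure, arc-length variation (grid arcs share one
length, so the length-based risk adjustment is uniform at +50%), spatially
correlated land-cover patches at realistic patch sizes, and real DEM
drainage. Passing oracle tests on these fixtures therefore certifies the
*algorithms* (exactness of frontier enumeration on additive nonnegative
attributes), not the ecological realism of any particular cost surface.

Three hand fixtures pin down reference behavior: `F1` (4-node chain, cost
arithmetic), `F2` (four-route frontier `{(1,6,1), (6,1,1), (2,2,9),
(4,4,4)}` whose `(4,4,4)` is unsupported, plus zero-cost wetland cycles and
degenerate anchors — one route minimizes two objectives), and `F3`
(biobjective frontier `{(1,3), (3,1), (2.5,2.5)}` with the interior point
unsupported).

## Problem sizes

The exhaustive oracle (all simple paths, dominance-filtered) is exact and
is the ground truth in every test; its cost grows exponentially, so oracle
comparisons run on 3×3-grid landscapes (9 nodes, two wetlands, well under
500 simple paths per OD pair) across 50 seeds, and the acceptance pipeline
demonstrates the full workflow on a 7×7 grid with four wetlands (49 nodes,
168 arcs, 12 ordered wetland pairs). Both solvers scale far beyond that —
the labeling search is polynomial in the number of labels — but exact
oracle verification is what bounds the test sizes.

## Known limitations

* Arc attributes must be nonnegative and additive; non-monotone or
  non-separable objectives are out of scope.
* MONISE-style enumeration finds extreme supported points; facet-interior
  (weakly supported) points are reachable only when a probe weight lands
  exactly on their facet and ties break their way, so on degenerate
  frontiers the supported count convention matters (the LP classifier
  counts facet-interior points as supported; on generic continuous-valued
  networks the two conventions coincide).
* The deposited-network adapter sniffs common column synonyms and fails
  loudly otherwise; it has been exercised against synthetic tables only.
* No raster preprocessing (DEM flow accumulation, polygon digitization);
  inputs are node/arc tables with raw or derived attributes.
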