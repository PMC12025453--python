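# Methods

## Model

`dsrank` scores node influence by evidence fusion. Each of m centrality
indicators, evaluated on every node of an undirected simple graph, is one
body of evidence about the hypothesis "node i is the influential one". The
frame of discernment is the node set; after column normalization each
indicator becomes a basic probability assignment (BPA) whose focal
elements are node singletons, and the indicators are fused with Dempster's
rule of combination.

Assumptions worth stating explicitly:

* **Singleton evidence.** Mapping a normalized column to singleton masses
  is the natural reading of "one column = one BPA over the nodes", and it
  makes the fused score equal to the normalized row-wise product of the
  normalized matrix. The consequence is deliberate and sharp: a node with
  zero support in any single metric (for instance, zero betweenness for a
  leaf) receives a DS score of exactly 0, regardless of its other metrics.
  Nodes tied at 0 are ordered by label. If *every* node has a zero
  somewhere, the evidence is totally conflicting and `ds_score` raises
  rather than returning an arbitrary ranking.
* **Scale invariance.** Column normalization absorbs any positive
  rescaling of a raw metric, so unnormalized degree/betweenness are used
  as-is; normalization conventions of individual metrics cannot change the
  DS ranking.
* **Order invariance.** Dempster's rule is commutative and associative,
  so the fold over columns is independent of metric order (property-tested;
  the default order is dc, cc, hcc, bc, pr, ec).

The general-subset combination engine is implemented in full — arbitrary
focal elements, conflict coefficient k, error on total conflict (agreement
mass ≤ 1e−12) — even though the pipeline only feeds it singletons; it is
the reference the singleton closed form is tested against. Numerically the
fused masses are renormalized by the accumulated agreement mass rather
than by 1 − k: the two are algebraically equal, but subtracting a conflict
near 1 cancels catastrophically. When k = 0 the products are returned
unnormalized, which keeps combination with the vacuous BPA bit-exact.

## Centrality conventions

* Degree, closeness, harmonic closeness and betweenness are exact
  (BFS-based); betweenness counts unordered pairs with endpoints excluded
  and no (n−1)(n−2) normalization.
* Closeness on disconnected graphs is computed within the reachable set
  and scaled by (r−1)/(n−1) (r = reachable count), giving finite,
  comparable values; isolated nodes score 0. Harmonic closeness handles
  disconnection natively (1/d = 0 when unreachable).
* The plain random-walk PageRank update diverges on bipartite graphs
  (e.g. stars), so the damped form with uniform teleport is the default:
  damping 0.85, tolerance 1e−10 on the successive L1 change, at most 1000
  sweeps, error on non-convergence. Damping → 1 recovers the undamped
  update wherever it converges.
* Eigenvector centrality is the dominant adjacency eigenvector
  (nonnegative, L2-normalized), computed by shifted power iteration so
  bipartite graphs converge too; it is undefined (error) on edgeless
  graphs. Residual ‖Av − λv‖/‖v‖ < 1e−8 is asserted on all test graphs.

## Targeted-attack protocol

Rankings are compared by static attack: the ranking is computed once on
the intact network and nodes are removed one per step in that order
(an adaptive mode that re-ranks after each removal exists behind a flag,
for exploration; it is off by default and the adaptive DS ranking can
legitimately fail on fragmented remnants through total conflict). After
each removal we record

* G = R/N — largest-connected-component fraction, and
* μ = 1 − η/η₀ — efficiency loss, η = (1/(N(N−1))) Σ 1/d_ij,

with N and η₀ frozen from the intact network and removed nodes
contributing nothing to η. Freezing N is what makes μ reach exactly 1 at
full dismantlement and keeps both curves monotone (G non-increasing, μ
non-decreasing), which the suite asserts for every strategy. Note that
with G defined against the original N, G = 0 occurs only when the last
node is removed; the informative comparison between strategies is the
mean of G over the removal sequence (reported by the acceptance script)
and the early shape of the curve.

## Visibility graphs

The natural visibility criterion is strict: observations a and b are
linked iff every intermediate c satisfies
x_c < x_a + (x_b − x_a)(t_c − t_a)/(t_b − t_a). A point exactly on the
chord blocks visibility, so collinear runs contribute only consecutive
edges; consecutive points are always linked. The production builder is an
O(n²) monotone-slope sweep — for a fixed left endpoint, b is visible iff
its chord slope strictly exceeds the running maximum slope to the
intermediate points — which is an exact restatement of the criterion, not
an approximation. A literal O(n³) triple-loop oracle is shipped alongside
and equivalence is asserted on random Gaussian, tied/rounded,
irregularly-spaced, convex and concave series. Node labels are 1-based
series positions. Edge sets are invariant under positive affine maps of
the values; the property test uses integer values with power-of-two
scale factors so the map is exact in floating point and strictness is
compared without rounding artifacts.

## Synthetic data and fixtures

The bundled Zachary karate-club fixture (34 nodes, 78 edges; diameter 5,
mean shortest path 2.408, mean clustering 0.571) is the canonical
published dataset and the main realistic test bed. Synthetic generators
(star, path, cycle, complete, Erdős–Rényi, Barabási–Albert) provide
topologies with hand-computable centralities; the BA generator uses the
standard star-seeded growth with m edges per new node (3(n−3) = 291 edges
at n = 100, m = 3) and is deterministic given a seed. These graphs lack
the community structure, degree correlations and weights of large
real-world networks, so green tests demonstrate correctness of the
computations and the protocol's invariants, not superiority of the DS
ranking on any particular real network. Random-graph checks (e.g.
degree-targeted vs. random attack on 20 Erdős–Rényi graphs with n = 100)
use fixed seeds throughout; problem sizes (1000 fusion matrices of shape
20×6, 100 oracle graphs with n ≤ 10, 100 visibility series of length 200)
were chosen so the whole suite runs in well under a minute of compute per
module while still exercising every code path.

## Known limitations

* Undirected, unweighted simple graphs only; no evidence weighting or
  alternative conflict handling (Yager, Murphy averaging).
* The zero-annihilation property of singleton fusion means sparse metrics
  (betweenness on trees) can zero out large parts of the ranking; ties at
  0 fall back to label order.
* The dolphin social network referenced alongside the karate club is not
  bundled; `load_fixture("dolphins")` raises unless the user supplies
  `dolphins.edgelist` from the published dataset.
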