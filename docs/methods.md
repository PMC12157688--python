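# Methods

## Model and assumptions

The package treats a cytometry sample as N independent events in D
display-transformed dimensions on the unit interval.  Its working
assumption is the one underlying manual projection pursuit: compensated /
unmixed marker dimensions measure largely independent molecular features,
so biologically distinct populations that are separable at all are
separable in some *pair* of dimensions, and a sequence of clean 2-D
splits loses nothing relative to higher-dimensional clustering.  All
statistical decisions are made on kernel density estimates whose sampling
variance is carried along explicitly; that is what permits a calibrated
test ("is this density dip real?") as the stopping rule, rather than a
heuristic cluster count.

Upstream steps are out of scope by design: compensation/unmixing,
live/dead and doublet pre-gating, and the choice of per-dimension
transform parameters are inputs, not outputs.

## Transforms and censoring

Raw intensities are mapped by the Parks–Moore logicle function, the
biexponential S(x) = a·e^{bx} − c·e^{−dx} − f parameterized by top of
scale T, decades M, linear width W and extra negative decades A, with
S(1) = T.  The forward transform inverts S by 100-round vectorized
bisection (interval width ≈ 10⁻³⁰, far below the 10⁻⁹ relative round-trip
tolerance asserted in tests).  W = 0 degenerates to a rescaled arcsinh
and is the mass-cytometry default (M = 4.3); the rescaling is fully
determined by the (T, M, A) config parameters.  After transformation any
event with a phenotyping value outside the closed interval [0, 1] is
removed entirely (not clipped), so the downstream grids never bounds-check;
the censored count is logged.  Non-phenotyping columns ride along
untouched for reporting.

## Dimension qualification

KL divergence of the sample from a reference law is estimated from the
order statistics by an m-spacing estimator with m = ⌈√n⌉ and
clamped edge indices, using the matched-count numerator (i₊ − i₋)/n.
The clamped numerator matters: with the naive 2m/n numerator the edge
bias alone is ≈ 0.01 at n = 1000, a quarter of the qualification
threshold.  Spacings are floored at the smallest positive double to keep
the estimator finite on ties.  References are the moment-matched normal
(always) and, in mass mode, the exponential with rate 1/mean fitted to
the **non-zero** values only — mass-cytometry negatives are a zero atom
plus a roughly exponential tail, and including the atom would make every
negative dimension "diverge" and defeat the filter.  Thresholds default
to 0.04 (normal) and 0.2 (exponential) and are exposed in config.
Dimensions with under 20 events or zero variance are unqualified without
error.  Pair enumeration guarantees at least one pair: all C(q,2) pairs
of the q qualified dimensions, else the single qualified dimension with
the best unqualified one, else the two most divergent dimensions; ties
break to the lower index.

## Density estimation

Weights are bilinearly binned onto a 257-node-per-axis grid
(spacing h = 1/256; 257 = 2⁸+1 keeps the cosine transform fast).  The KDE
is computed spectrally: DCT-I of the weights, damping of coefficient
(kₓ, k_y) by exp(−½(πW)²(kₓ²+k_y²)), inverse DCT-I, then division by
n·h².  This is *exactly* discrete convolution with the reflected
(periodized) Gaussian sampled on the grid — the aliasing gap is
exp(−½(πW(G−1))²) < 10⁻¹³ at every supported W — which is why the test
oracle, a direct image-sum convolution, matches to machine precision
rather than "approximately".  Tiny negative ringing (≈ −10⁻¹⁸) is clipped
to zero to preserve the nonnegativity invariant.

The variance pass exploits K_W² ∝ K_{W/√2}: smoothing the weights with a
Gaussian of SD W/√2 and scaling by 1/(4πW²h²) gives V with
Var[f̂(x)] ≈ V(x)/n², the standard squared-kernel KDE variance with the
bias term dropped.  The width-doubling identity (the squared-kernel pass
at 2W equals the plain pass at W√2 up to a constant) is kept as a
regression test; the implementation recomputes rather than caches, since
the pass costs a few milliseconds.

Initial W is 0.01 of full scale for fluorescence and 0.025 for mass data.
Anything much below 0.01 is meaningless on a 257 grid (the kernel would
be under two grid cells wide); the mass default reflects the heavier
discreteness of mass-cytometry low ends.

## Modal clustering and the noise floor

The noise floor guards against counting noise founding clusters in
sparse regions: grid points are sorted ascending by density, a window of
round((4W(G−1))²) points — the ±2W kernel spot — slides upward, and the
floor is the highest density inside the first window whose summed event
weight exceeds σ² (σ = 3, i.e. more than 9 events).  The "highest density
inside the window" reading is one of several the window rule admits; it
is the conservative one and is fixed here (and in the sliding-window test
oracle).  If no window qualifies the pair yields no clusters.

The sweep then classifies grid points in descending density order (ties
broken by row, then column — determinism requires a rule): a point with
no classified 4-neighbor founds a cluster; one whose classified
4-neighbors span two clusters becomes boundary; a point whose only
classified neighbors are boundary points is itself boundary (the chosen
resolution of a case the sweep rule leaves open — it keeps valleys thin
and never founds a mode beside a boundary).  Each classified point marks
seven of its eight neighbors contiguous, omitting one diagonal on a
rotating modulo-4 counter for radial symmetry.  Points below the floor
are classified outward in contiguity layers, attaching them to the
nearest significant cluster; a stalled layer (pathological geometry)
falls back to nearest-classified-neighbor assignment rather than
failing.  More than 12 clusters signals the caller to double W and
restart from the weights.

Boundary points adjacent to three or more clusters become graph
vertices; those adjacent to exactly one (spurs at the grid border) are
absorbed into that face; the rest, grouped by separated pair and
8-connectivity, are ordered into chains by a greedy endpoint walk.  Each
chain is an edge carrying its maximum density (the saddle) and its
argmax point.  More than 32 edges (the bit-vector capacity) likewise
signals widening.

## Density-based merging

Edges are tested in descending saddle order.  The dip statistic for each
adjacent mode is t = (f̂_mode − f̂_saddle)/√(V̂_mode + V̂_saddle); the edge
survives only if *both* modes give t > z (z = 3 by default, matching σ).
Requiring both is the conservative reading and is switchable
(`dbm_require_both=False`).  On removal the two faces merge, the merged
mode is the denser of the two, edges now joining the same face pair
splice (saddle = max over the combined chains), and the scan restarts —
the restart matters because merging changes mode identities.  The z = 3
calibration is validated behaviorally: on a single Gaussian at n = 500
with a deliberately narrow kernel the false-split rate is ≈ 0% (bound:
≤ 10%), while a genuinely separated mixture at n = 5·10⁴ retains its
valley in 100% of seeded runs, and retention is monotone in n on a
shallow 4-SD valley (0/15 → 1/15 → 15/15 over n = 200/2000/20000).

## Dual-graph enumeration

Candidate separations must be continuous curves dividing the clusters
into two contiguous regions.  They are enumerated abstractly on the dual
graph: a node per face (one bit each), an edge per boundary (one bit per
cluster-graph edge).  Removing a dual edge merges its endpoint node
bitsets; dual edges that then join the same node pair fuse by OR of
their edge bitsets — the geometric counterpart is splicing boundary
chains at a vanished vertex.  Parallel dual edges are fused eagerly,
including at construction.  A stack search pops a graph, emits it as a
candidate when a single dual edge remains (its edge bitset is the
boundary; its endpoint bitsets are the two sides), and otherwise pushes
one child per removable edge.

The ordering rule that makes the search complete and duplicate-free:
an edge is removable iff the **lowest** set bit of its edge bitset
exceeds the lowest bit of every edge removed so far.  Any reachable
final partition has exactly one admissible removal sequence (each step
must remove the fused chunk containing the smallest remaining internal
edge, and that chunk is unique), so each candidate is emitted once.
Comparing against the highest removed bit instead — the superficially
natural reading — is *incomplete* once fused chunks carry
non-contiguous bits; the brute-force contiguous-2-partition oracle on
random planar cluster graphs (both sides connected, boundary points one
8-connected curve) distinguishes the two rules immediately and pins the
implemented one.

## Scoring, selection, recursion

A candidate's score is n·2W·∮f̂ ds along its chains (trapezoid over grid
points): the approximate number of events within a ±W strip of the
border, the proxy for misallocated events.  Best-separation mode
minimizes the score; best-balance divides it by 4P(1−P) first, P being
the in-side event fraction ("in" = the side holding the lowest-numbered
face, an orientation convention).  Events split by grid-cell ownership of
the face labels — boundary cells resolve to the lowest adjacent face —
not by point-in-polygon on the simplified output polygon, which is
presentation only.  Ties break lexicographically: lowest dimension pair,
then lowest boundary bitset.  Recursion stops per branch when no pair
yields a candidate or a population falls below the absolute/relative
minimum size (both default off).  By default an undersized *child*
simply becomes a leaf; `min_stop_strict=True` instead refuses the split.
The per-pair analyses are pure functions of (events, dims, config) and
are executed sequentially; determinism across runs is a tested
invariant, and a parallel scheduler would not change any result.

Leaf labels are heuristic: at each ancestor split the one or two
phenotyping markers with the largest sibling mean difference are
annotated +/− for the side taken; deeper splits override earlier
annotations of the same marker.  They are mnemonics, not biological
assessments.

## Output

The gating tree serializes as versioned JSON (`epp_tree_v1`), with
boundary polylines simplified by Ramer–Douglas–Peucker at 1% of scale by
default (tests bound the induced reclassification disagreement at 1%).
Scores are serialized as the approximate event counts described above
and documented as approximate.  The assignment CSV
(`event_id,leaf_id,mahalanobis`) gives each non-censored event its leaf
and the Mahalanobis distance from the leaf mean over the phenotyping
dimensions, with ridge 10⁻⁶·trace/D on the covariance and a diagonal
fallback if still singular.

## Similarity coefficients

For validating one labeling against another: the match table
cross-tabulates shared events; Jaccard is |A∩B|/|A∪B| (0 when both
empty, by convention); central similarity trims each set independently
to its central 80% by Mahalanobis distance from the set's own mean and
computes Jaccard restricted to the union of the cores, discounting
disagreement confined to distribution tails.  Per-set trimming (rather
than joint) is the chosen reading of "central 80% of events in A or B";
the trim fraction is a parameter.

## The synthetic generator

Fixtures emulate display-transformed data: mixtures of diagonal-
covariance normals truncated to [0,1] by rejection (clipping would pile
mass on the boundary and distort the marginals), with known component
labels; mass-like dimensions replace a marginal with a zero atom plus an
exponential tail at the bottom of scale.  Canonical fixtures are
versioned constants: component SD 0.03 with mean separations ≥ 0.4
(≥ 13 SD — misassignment probability is negligible, which is what makes
the ≥ 99% purity assertions sharp); `tiny_plus_overlap` adds a 2%
satellite to two 5.8-SD-separated majors to contrast the selection
modes; `pair13_only` hides the separation from one dimension pair;
`many_spikes` packs 15 tight spikes into three groups to force adaptive
widening.  What the generator does **not** emulate: spectral spillover
and compensation artifacts, acquisition-time drift, doublets, non-normal
skewed populations, and correlated (non-diagonal) within-population
covariance.  Passing tests therefore demonstrate the algorithm's
correctness and calibration under its own model, not performance on
instrument data.

## Problem sizes and numerical choices

Test and acceptance runs use n = 10³–10⁵ events and 50–100 seeded
replicates per calibration rate — sizes at which every rate in the
acceptance report is stable to the digit across seeds.  Degenerate
inputs are values, not errors: empty tables, all-zero weight grids,
single-face graphs, and absent separations all flow through as "no
split".  Floating-point guards: constant dimensions are detected at
sd ≤ 10⁻¹²·max(1,|mean|); KDE output is clipped at zero; spacing and
covariance denominators are floored/ridged as described above.

## Known limitations

Separations that exist only in 3 or more dimensions jointly are
invisible by construction.  The boundary-chain walk is greedy and can in
principle mis-order a pathologically thick boundary (the kernel-widening
escape hatch covers the cases we can construct).  The 32-edge bitset
capacity caps graph complexity per pair; wider builds would be a
mechanical change.  Leaf labels are cosmetic.  FCS support covers the
common single-dataset float/double/integer layouts of FCS 3.0/3.1, not
multi-dataset files or bit-packed integer widths.
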