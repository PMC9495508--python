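# Methods

## Problem and model

A backbone phylogeny `T` with branch lengths defines a metric on its leaf
set: `dT(i, j)` is the path length between leaves `i` and `j`.  Given one
aligned gene per leaf, `hyperplace` learns an embedding function `phi` from
sequence space into a constant-curvature space such that the embedded
distances reproduce `dT`.  New (query) sequences aligned to the backbone
are pushed through the same map, giving query-to-backbone distance
estimates that feed distance-based placement and tree extension.  The
setting of interest is *discordant* placement: the backbone is a species
tree while the sequences evolve on gene trees that disagree with it
(incomplete lineage sorting and similar processes), which is why distances
are learned from the backbone rather than computed directly from the
sequences.

Trees embed poorly in low-dimensional Euclidean space — a balanced binary
tree needs dimension growing with its size for isometric embedding —
whereas hyperbolic space embeds trees with arbitrarily low distortion in as
few as two dimensions, because the volume of a hyperbolic ball grows
exponentially with its radius.  The package therefore supports three
geometries behind one interface:

* **'Loid** (hyperboloid / Lorentz) model, the default: points `x` in
  `R^{d+1}` with `x^T H x = -1`, `x_0 > 0`, `H = diag(-1, 1, ..., 1)`;
  distance `acosh(-x^T H y)`.  Its distance function has no boundary
  singularity, which makes optimisation stable.
* **Poincare ball**: the open unit ball with
  `d(x, y) = acosh(1 + 2|x-y|^2 / ((1-|x|^2)(1-|y|^2)))`.
* **Euclidean** baseline, where the *squared* Euclidean distance plays the
  role of the metric (the convention of flat-space tree embedding).

The encoder is a Euclidean convolutional network; its `d`-dimensional
output is lifted onto the manifold by the exponential map at the base
point — `tanh(|v|)/|v| * v` for the ball, `(cosh|v|, sinh|v| * v/|v|)` for
the hyperboloid.  All hyperbolic computation happens at unit curvature; an
arbitrary curvature `C = -1/s^2` is carried by a single positive scale `s`
multiplying all pairwise distances.  This reparameterisation keeps the
domain of every distance function fixed while the curvature is learned.

## Loss and alternating optimisation

Training minimises the mean squared *relative* distance error over
distinct leaf pairs,

    cost(phi, s) = mean_{i<j} ( s * d(phi(s_i), phi(s_j)) / dT(i, j) - 1 )^2,

a weighted least-squares criterion in which every pair contributes its
fractional deviation, so small distances matter as much as large ones.
For fixed `phi` the cost is convex in `s` with closed-form minimiser
`s* = E[rho] / E[rho^2]`, `rho = d/dT`.  The loop alternates: a stochastic
gradient step on the network at the current `s`, then a relaxed scale
update `s_{k+1} = s_k + alpha_k (s* - s_k)` computed from the same batch
(per-batch by default; a per-epoch variant is available).  `s` receives no
gradient of its own.

Two numerical safeguards come from the precision analysis of hyperbolic
space.  First, the largest unit-curvature distance representable by points
with `|x|^2 <= 1 - 10^-p` is `2 acosh(1 + 2(1-10^-p)/10^-p)`, roughly
`4 ln 2 + 2 p ln 10` — only ~58 at `p = 12`, i.e. double precision cannot
hold trees of large diameter near the boundary.  Tree distances are
therefore normalised to a maximum of 1 before training, and the factor is
absorbed into the scale (and restored whenever distances are reported).
Second, the learning rate decays exponentially,
`alpha_k = alpha_0 * 0.95^floor(k/10)`, so that late training can refine
the small distances without destabilising the large ones.

Mini-batches are a fresh uniform partition of the taxa each epoch
(default size 32; 64 often gives the lowest distortion); all `C(B,2)`
within-batch pairs enter the loss, and pairs are never formed across
batches.  A consequence worth knowing: a fixed pair fails to share any
batch over `E` epochs with probability about `(1 - B/N)^E`, non-negligible
for large backbones — `evaluation.cobatch_never_probability` computes it
(an exact partition version is provided alongside).

An optional pseudo-count adds a constant to every terminal branch, lifting
near-zero leaf distances (every leaf pair grows by exactly twice the
pseudo-count); identical training sequences are rejected by default since
they make relative error against a zero distance undefined.

## Encoder architecture and training defaults

The encoder is the same shape throughout: one-hot input (4 channels x L
sites; gaps and ambiguity codes become the uninformative column 1/4 each),
three linear 1-D convolutions with kernel sizes 1, 5, 5 and 'same'
padding, an additive skip from the second layer's output into the third
(a residual block), ReLU between blocks (configurable), then a dense layer
to `R^d`.  Forward and backward passes are written directly in NumPy
(im2col convolutions, analytic Jacobians of the hyperbolic distances with
respect to the tangent outputs); gradient correctness is pinned by
finite-difference tests.

Defaults, with reasons:

| parameter | default | rationale |
| --- | --- | --- |
| channels | (16, 16, 16) | ample capacity for backbone memorisation at desk scale; wider nets gave no measurable accuracy gain on the synthetic benchmarks while costing ~10x CPU time |
| embed_dim `d` | 128 | matches common practice for large backbones; the desk-scale studies use `d = 2` explicitly |
| optimizer | Adam, `alpha_0 = 1e-3` | the dense layer's fan-in (channels x L) makes a single global SGD step size ill-conditioned across layers; plain SGD remains available (`optimizer="sgd"`) |
| epochs | 1000 | loss plateaus well before this on the benchmark sizes |
| batch size | 32 | standard default; 64 recommended when distortion of small distances matters |
| decay | `p = 0.95` every `K = 10` epochs | exponential schedule above |
| initial scale | `s*` of the untrained embedding | the closed form gives the best start for free |

Weights are fan-in-scaled Gaussian, biases zero, all float64, fully
deterministic given the seed.

## Placement and tree updating

`placement.query_distances` embeds backbone and queries jointly and
returns `normalization_factor * s * d_unit` — distances in original tree
units.  `placement.place_query` is a deliberately simple distance-based
placement, not a re-implementation of a production placer: candidate
edges are those on paths among the `b = 5` nearest references plus all
edges incident to those paths; each candidate edge is scored by a
two-parameter weighted least squares (pendant length >= 0 and attachment
offset clamped to the edge) against the model distances to the
references, weighted by inverse squared model distance to match the
relative-error training objective (unweighted optional).  Two pragmatic
refinements keep the solver exact in the additive-distance limit: if the
restricted candidate set fits poorly, the search widens to all edges; and
if several edges tie (which happens exactly when all `b` references sit
on one side of the attachment), the tied comparison is re-run against the
full reference set, which always spans both sides.  Ties that survive
resolve to the smallest canonical edge id.  Production placement with
external tools remains the intended path at scale: the PHYLIP square
matrix export is accepted by APPLES-2 and FastME.

For tree *updating* (extending the backbone into a fully resolved tree
containing the queries) the package builds a hybrid matrix: exact tree
distances for backbone-backbone pairs, embedding distances for every pair
involving a query.  With several genes, one model is trained per gene and
the matrices are merged entrywise by the median (lower median for even
counts, for determinism) — the median is what confers robustness to
highly discordant outlier genes.

Placement error is counted topologically: the number of edges between the
placed edge and the edge the query truly attaches to (0 = exact).  Edges
are identified by the child node in canonical post-order, and compared
across trees by their leaf-set bipartitions on an unrooted view (a
degree-2 root's two edges count as one).

## Evaluation metrics

`weighted_se(d_est, d_true) = (d_est/d_true - 1)^2` is the squared
relative deviation.  `distortion_report` returns plain MSE, weighted MSE,
the *median* weighted SE (robust to the rare pairs with enormous relative
error), and the fraction of outliers — pairs with weighted SE strictly
greater than 100.  Outliers can optionally be excluded from the MSE
figures; they always count in the median and the outlier fraction.
`split_small_large` separates each taxon's `k = 5` smallest true
distances from the rest, because distance-based placement relies almost
entirely on the small ones.  Tree accuracy uses Robinson-Foulds distance
(raw split count, normalised by `2(n-3)` or by the observed split count)
and a quartet distance estimated by Monte-Carlo sampling of 4-leaf
subsets (exhaustive below 16 leaves); the exact `O(n log n)` quartet
algorithm is out of scope, and the sampling error is quantified in the
tests.

## Synthetic data: what it emulates, and what it does not

The generator produces the full study setting without external data: a
species tree (backbone), a gene tree made discordant by a configurable
number of random NNI moves, a gap-free alignment evolved on the gene tree
under Jukes-Cantor, and a random query holdout.

* Trees: uniform coalescent-style joins with i.i.d. exponential branch
  lengths (mean 0.1 substitutions/site — pairwise distances mostly 0.1-1.5,
  where JC sequences of a few hundred sites are informative), plus
  perfectly balanced and caterpillar shapes for controlled geometry.
* Discordance: NNI moves are a structural stand-in for incomplete lineage
  sorting — they give controllable topological disagreement (at most one
  split per move) without a population-genetic model.  No multispecies
  coalescent simulation is attempted.
* Sequences: strict Jukes-Cantor — uniform root, per-site change
  probability `3/4 (1 - e^{-4t/3})` per branch; no indels, no rate
  heterogeneity, no alignment error.  Gap handling in the encoder is
  exercised by hand-written fixtures instead.

Passing tests on these data demonstrate that the optimisation machinery
recovers tree metrics from sequence data at desk scale and that hyperbolic
geometry dominates the Euclidean baseline at low dimension.  They do not
demonstrate robustness to the full messiness of real marker-gene data
(fragmentary sequences, alignment error, paralogy, rate variation), and
the benchmark sizes (16-32 leaves, 500 sites, d = 2) are far below the
tens of thousands of taxa the approach targets in production.

## Numerical choices and degenerate inputs

* `acosh` arguments below 1 by at most 1e-9 are clamped to 1 (round-off
  near coincident points); larger violations raise, since they indicate a
  constraint violation rather than noise.
* Hyperboloid membership is enforced to 1e-6; the constraint residual of
  `cosh^2 - sinh^2` grows with the point's norm in double precision, which
  is exactly why distances are normalised before training.
* Coincident embedded points have zero distance and zero gradient (the
  distance is non-differentiable there; the subgradient 0 is used).
* The exponential maps are taken verbatim with argument `sqrt(-C)|v|`
  (not the half-argument variant); any constant factor is absorbed by the
  learned scale.
* Zero tree distances among distinct taxa abort training with a pointer
  to pseudo-counts; an all-zero distance matrix cannot be normalised.
* Non-finite losses abort with a diagnostic rather than continuing.
* Query counts for fractional holdouts round half up; clade holdouts are
  sampled greedily among eligible disjoint clades and fail loudly with
  the achievable count when too few exist.

## Known limitations

* Training cost is dominated by the NumPy convolutions; the package is
  CPU-bound and meant for desk-scale experiments and method study, not
  for 10^4-taxon production backbones.
* The built-in placer is a least-squares stand-in; no minimum-evolution
  criterion, no divide-and-conquer.  Export the distance matrices for
  production placement.
* The hybrid update matrix is produced, but tree inference from it (e.g.
  FastME) is external by design.
* Only strict Jukes-Cantor simulation and distance estimation are
  provided; more elaborate substitution models are out of scope.
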