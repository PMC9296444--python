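# Methods

This note documents the models, conventions and design choices behind
`dreval`: what each metric computes, what the synthetic generators emulate,
which numerical decisions were pinned where a convention was genuinely
open, and what passing tests do and do not establish.

## Data model and distances

All matrices are point-major (rows = cells/points). Distances are Euclidean
throughout. Nearest neighbors are computed **exactly** (blocked full
distance matrix, stable argsort) with ties broken by the lower point index.
Approximate neighbor search would be faster at scale but makes metric
values non-deterministic; for an evaluation framework, determinism wins.
Point indices are 0-based in memory; class labels read from files are
re-coded to dense integers 1..M in first-appearance order, with the
original tokens kept in a sidecar mapping.

## Local structure metrics

**Supervised accuracy.** A stratified random split (90/10 by default,
seeded) partitions the labeled points; the classifier sees only the 2-D
embedding coordinates. Two classifiers are offered:

- *SVM with RBF kernel* at library-default regularization — no
  hyperparameter search, since the goal is a comparable score across
  embeddings, not the best classifier. An optional training-subsample cap
  (default 10 000) bounds the quadratic SVM cost; when applied it is
  recorded in the report parameters.
- *k-NN (k = 5)* implemented in-package rather than via a library
  classifier, because the degenerate cases require a pinned tie policy:
  neighbor ties break by lower training index; vote ties go to the label
  of the nearest neighbor among the tied classes, then to the lower class
  id. With these rules the prediction on fully degenerate inputs (all
  points coincident) is a deterministic function of the split.

Classes with fewer than 2 members force a fall-back to an unstratified
split (with a warning); a single-class input yields a degenerate report
flagged as such rather than an error.

**Neighborhood preservation.** The average over points of
`|N(i) ∩ N′(i)| / k` with k = 5 by default. Because both neighbor sets come
from exact, deterministic k-NN, the metric is invariant under any
similarity transform applied to either space independently.

## Global structure metrics

**Random triplet accuracy.** Sampling is *anchored*: every point serves as
the anchor of `triplets_per_point` (default 5) triplets whose two other
members are drawn uniformly without replacement, from a seeded generator.
A triplet agrees when the sign of `d(i,j) − d(i,k)` matches across spaces;
exact ties (sign 0) agree only if tied in both spaces — a measure-zero
event for continuous data that matters only for degenerate fixtures. An
exhaustive enumerator over all `n(n−1)(n−2)/2` anchored triplets serves as
the oracle for the sampled estimator and is guarded at n ≤ 500.

**Distance Spearman correlation.** All pairs are used when
`n(n−1)/2 ≤ pairs_sample_size` (default 100 000); otherwise a seeded sample
of condensed pair indices without replacement. Rank correlation uses
average ranks for ties. If either space has constant pairwise distances the
correlation is undefined; the report then carries NaN plus a reason rather
than silently producing a number.

**Centroid-based metrics.** Class centroids are arithmetic means in each
space's own coordinates. KNC preservation uses the class-count-adaptive
neighbor count `k = max(1, ⌊(C + 2)/4⌋)`, which keeps the metric comparable
across datasets whose class counts range from a handful to dozens (the
formula already gives 1 for C ∈ {2, 3}; the max-guard only protects
misuse). Nearest-class lists use the same stable tie-break as point-level
k-NN. Centroid distance correlation is the Spearman correlation over all
`C(C−1)/2` centroid pairs and requires C ≥ 3.

## Synthetic benchmarks

The generators are pure functions of their configuration (seed included).

**Gaussian Linear** (defaults: 20 clusters × 100 points, 50-D,
spacing 5, σ = 1): cluster means sit at `j · spacing · u` for a random unit
vector `u`, so the population means are exactly collinear; points add
isotropic Gaussian noise. The chain ordering of clusters is the global
structure a good embedding should retain. The line direction is random per
seed; spacing/σ = 5 gives visibly chained but distinguishable clusters.

**Hierarchical Gaussians** (defaults: 5 macro × 5 meso × 5 micro = 125
micro clusters × 40 points, 50-D): micro-cluster centers are built
additively — a random unit direction scaled by 30 for the macro level,
plus one scaled by 8 for the meso level, plus one scaled by 2 for the
micro level — with point noise σ = 0.5. The strict ordering
macro > meso > micro of offset magnitudes creates structure at three
separated length scales; the three label vectors nest by construction and
are validated on every bundle. All counts and scales are parameters, so
alternative hierarchy shapes can be generated.

**Blobs**: rejection-sampled cluster means at pairwise distance ≥
`separation` with isotropic noise — a fixture for supervised metrics where
perfect classification is achievable by construction.

What the generators do *not* emulate: count noise (no negative-binomial
sampling), dropout, batch effects, or manifold structure beyond Gaussian
clusters. Passing metric tests on these benchmarks demonstrates that the
*metrics* behave correctly (identity scores 1, chance scores ½, structure
destruction is detected); it does not certify any DR method's behavior on
real scRNA-seq data.

## Pre-processing chain

`log_normalize` divides each cell's counts by the cell total, multiplies by
`scale_factor` (default 10 000), and applies the natural log with
pseudocount 1 (`log1p`) — the convention of the standard single-cell
toolkits. HVG selection ranks features by the variance of standardized
values: observed per-feature means and variances, an expected variance from
a lowess regression (span 0.3, robustifying iterations on) of
log10 variance on log10 mean across features, standardization by
`(x − mean)/√(expected variance)` and symmetric clipping at ±√n. With few
features the local trend can absorb an isolated feature's own variance;
this is inherent to trend-based standardization and is documented rather
than patched. `scale_center` uses the sample (1/(n−1)) standard deviation;
zero-variance features map to zeros. PCA uses a full SVD (deterministic)
for problems with min(n, d) ≤ 3000 and the seeded randomized solver
otherwise, with component signs fixed so the largest-magnitude loading is
positive — both solvers therefore give bitwise-reproducible scores.

## Harness

Adapters are registry entries `(X, params, seed) → n × 2 array`. The
built-in `pca` and `identity2d` adapters are always available and
deterministic; t-SNE (scikit-learn) and UMAP register when importable.
Wall-clock runtime (monotonic clock) spans the adapter's entire transform,
so internal graph construction is charged to the method; runtimes are
reported but never asserted against.

The ForceAtlas2 protocol builds the undirected union k = 5 nearest-neighbor
graph (edge iff either endpoint is among the other's k nearest neighbors),
initializes from the first two principal components rescaled so PC1 has
standard deviation 100 (the order of the layout's native coordinate
scale), and runs a fixed iteration count (default 750) at backend defaults.
With `iterations=0` the scaled initialization itself is returned, which
exercises the full input protocol without a layout backend; with
iterations > 0 an importable `fa2`/`fa2_modified` package is dispatched to,
and a clear registry error is raised otherwise.

The 5-run protocol varies **only the method seed** across repeats, holding
the metric-evaluation seed (triplet/pair sampling, train/test split) at the
base seed. Run-to-run spread therefore measures backend stochasticity
alone, and a deterministic backend yields std exactly 0 on every metric.
With a single run, std is reported as 0 by convention.

Sensitivity sweeps operationalize parameter/PC-count/pre-processing
robustness as *metric dispersion*: max − min of the per-setting metric
means, plus the pooled per-setting std. This is an artifact-level summary
of what is otherwise a qualitative judgment (does the picture change when
the knob moves?); dispersion 0 for a single-setting grid is an invariant,
and dispersion is monotone under grid refinement. Failed grid cells are
recorded and skipped, not fatal. The GLM-PCA pre-processing variant
consumes a pre-computed factor matrix from disk; GLM-PCA itself is not
re-implemented.

## Problem sizes and limitations

The bundled experiments run at desk scale by design: identity and oracle
checks at n ≤ 200, null baselines at n = 1000, the ranking experiment on
the default hierarchical benchmark (n = 5000), pre-processing determinism
at 500 cells × 3000 genes. Exact k-NN is O(n²d) and the package is not
intended for million-cell matrices without swapping in an approximate
index, which would trade away determinism. Supervised metrics inherit the
usual caveats of label-based evaluation (label noise, class imbalance);
the centroid-based metrics assume classes are unimodal enough for a
centroid to be meaningful.
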