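# Methods

## Problem and model

Spatial domains are spatially coherent tissue regions — cortical layers,
tumor compartments, immune aggregates — composed of multiple cells or
spots.  `nichespan` detects them jointly across several tissue slices by
representing every observation not by its expression profile but by the
cell-type composition of its spatial *niche*:

- **Niche.**  At single-cell resolution, an observation's niche is itself
  plus its `k` nearest neighbors by planar Euclidean distance (default
  `k = 30`).  At spot resolution — where spots sit on a regular grid — the
  niche is itself plus all spots strictly closer than
  `radius_multiplier × grid_unit` (default multiplier 2), where
  `grid_unit` is the median distance from a spot to its nearest other
  spot.
- **Embedding.**  The embedding row of an observation is the arithmetic
  mean of the annotation rows over its niche: a probability vector over
  cell types.  One-hot labels yield niche type frequencies; deconvolution
  proportions yield averaged proportions.
- **Joint detection.**  Because all slices share one ordered cell-type
  vocabulary, per-slice embeddings concatenate into a single comparable
  matrix.  Pairwise dissimilarities (Jensen–Shannon divergence by
  default) feed agglomerative clustering (complete linkage by default);
  cutting the tree at `N1` clusters defines the domains, each named
  `Domain_{N1}_{N2}` with `N2` ordered by decreasing size.  Domains are
  then backtracked to their slices of origin.

The divergence between two composition vectors P and Q is

    JSD(P, Q) = (KL(P, M) + KL(Q, M)) / 2,   M = (P + Q)/2,

with KL(P, Q) = Σ P_i ln(P_i/Q_i) and 0·ln 0 = 0.  Natural logarithms are
used, so 0 ≤ JSD ≤ ln 2 ≈ 0.6931; any other base only rescales the matrix
and changes no ranking or clustering (switchable via `base=`).  The
mixture M keeps JSD finite for all simplex inputs, so no pseudocounts are
needed; raw KL is exposed only under its support precondition and raises
on infinite divergence.  Manhattan, Euclidean, cosine, Pearson and
Spearman (average-rank ties) are drop-in alternatives; the latter three
are similarities converted through `1 − similarity`, and rows with
undefined correlation (zero variance) get similarity 0 with a logged
warning rather than aborting.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 30 | KNN niche size at single-cell resolution |
| `radius_multiplier` | 2 | radius niche reach, in grid units (multiplier 1 on a regular grid degenerates to self-only niches, i.e. the spot's own annotation) |
| `include_self` | True | whether the observation belongs to its own niche |
| `metric` | `jsd` | dissimilarity between embedding rows |
| `linkage` | `complete` | agglomeration rule (also `average`, `ward`) |
| `n_domains` | `auto` | resolution `N1`; integer or adaptive selection |
| `deep_split` | 2 | sensitivity of the adaptive selection (0–4) |
| `min_cluster_size` | 20 | clusters smaller than this (capped at n/2) are absorbed |

Self-inclusion is a convention (the niche literature is split); with it,
`radius_multiplier = 1` reduces exactly to the spot's own deconvolution
vector, which is the documented baseline behaviour of radius-1 niches.
KNN distance ties break by ascending observation index so results are
platform-independent; duplicate coordinates are legal distance-0
neighbors under the same rule.  The strict radius cutoff carries a 1e-9
relative guard so grid points at exactly the cutoff distance stay
excluded despite floating-point rounding.

## Automatic choice of the number of domains

`auto_domain_number` is an adaptive gap cut in the spirit of dynamic tree
cutting, implemented directly on the linkage tree (no external
tree-cutting package is used):

1. For every candidate resolution `k ≤ n/2`, the width of the
   merge-height window that yields exactly `k` clusters is computed; the
   candidate with the widest window (largest height gap) is selected.
2. The candidate is accepted only if it looks like genuine structure
   rather than an arbitrary slice through a homogeneous cloud, via two
   tests controlled by `deep_split`: the clusters' internal diameter (the
   height just below the cut) must be at most a fraction of the merge
   height just above it (0.35 at level 2), and the mean between-cluster
   distance must exceed the mean within-cluster distance by a relative
   margin (0.85 at level 2).  Failing either test returns 1: the tree is
   a single homogeneous domain.
3. Clusters smaller than `min_cluster_size` are absorbed into their
   siblings and not counted, so a handful of stragglers cannot inflate
   the resolution.

The two thresholds separate cleanly in practice: homogeneous niche clouds
show diameter ratios ≥ ~0.43 and separations ≤ ~0.77, while genuinely
separated domains show ratios ≤ ~0.23 and separations ≥ ~0.99, so the
level-2 defaults sit between the regimes with margin on both sides.
Levels 0–4 interpolate from conservative (0.15/0.95) to eager
(0.60/0.50).

## Reference-based annotation

A spatial reference reduces a domain-annotated data set to one centroid
per domain (mean embedding row of its members; still a simplex vector).
Query observations are annotated in four steps: build centroids, embed
the query, compute JSD from every query row to every centroid, assign the
argmin (ties to the first-listed domain).  The achieved minimum is
reported as a confidence score in [0, ln 2], 0 only for exact centroid
matches.  Query columns are harmonized to the reference vocabulary by
name: missing types are zero-filled, query-only types are dropped and the
rows renormalized (a row left with no mass falls back to uniform, with a
warning).  There is no rejection by default — the minimum is assigned
unconditionally — but `max_jsd` optionally labels poor matches
`unassigned`.

## Slice-level clustering

Slice i is summarized by its spatial-domain composition
`C^i = [D_ij / M_i]`, j = 1..N over all detected domains, with `D_ij = 0`
for domains absent from the slice.  Hierarchical clustering of these raw
simplex rows (Euclidean/complete by default, matching common
heatmap-clustering defaults; JSD also valid) groups slices by shared
spatial organization.  Rows are deliberately not rescaled or z-scored.
The spatially blind baseline replaces `C^i` by the slice's mean cell-type
annotation row; the bundled confound scenario (identical 50/50 global
type mix, segregated vs mixed arrangement) is constructed so that the
baseline carries no signal while domain composition separates the groups
exactly.

## Evaluation metrics

ARI is evaluated exactly from the contingency table
(`Σ_ij C(n_ij,2)` corrected by the expected index and normalized by the
max index); a 0/0 arises only when both partitions are trivial, which
means they are identical, and returns 1.  macro-F1 averages per-domain
F1 over the **distinct truth domains** (not the label union); undefined
precision or recall (zero denominator) contributes 0 with a warning, so a
degenerate single-domain prediction scores low rather than erroring.
Both are cross-checked in the test suite against brute-force pair
counting / confusion-matrix oracles and scikit-learn.

## Synthetic data: what it emulates and what it does not

The generator draws domains as uniform points in non-overlapping bands
(layered, cortex-like) or discs (focal, immune-aggregate-like), with cell
types i.i.d. from per-domain compositions; shared domains repeat across
slices with identical compositions, a rare domain can be restricted to a
subset of slices, and per-slice scale factors create condition groups
with distinct domain mixes.  Spot resolution aggregates sampled cells
onto a square grid (spot = occupied bin center, annotation = within-bin
type frequencies, optionally jittered by a Dirichlet draw centred on the
true mix; truth = within-bin majority domain).  Perturbations are
exact-count: label noise reassigns exactly `round(rate·n)` observations
to a uniformly random *different* type; dropout zeroes exactly
`round(rate·nnz)` nonzero expression entries.  All streams derive from a
mandatory seed (per-slice via `SeedSequence((seed, slice_index))`) and
are bit-reproducible.

The bundled scenarios place domains with spatial margins larger than the
niche reach and with strongly distinct compositions — the well-separated
regime in which recovery is exact and any degradation is attributable to
the injected perturbation.  Real tissue violates this: adjacent domains
share boundaries, so boundary niches mix compositions and boundary
observations are intrinsically ambiguous; annotations carry structured
(not uniform) error; spot deconvolution error is not Dirichlet.  Passing
tests therefore demonstrate correctness of the machinery and its noise
response, not expected accuracy on real data.  The dropout utility
corrupts an expression matrix directly; it does not rerun upstream cell
typing on the corrupted matrix, which is the fuller experiment one would
perform with real annotation pipelines.

## Numerical choices and degenerate inputs

- Annotation/embedding rows must sum to 1 within 1e-8; proportion tables
  are silently renormalized only within 1e-3 of 1 (deconvolution output
  is near-simplex but rarely exact), beyond that it is a data error.
- Cell-type columns are ordered lexicographically over the union across
  slices; missing types are zero-filled.  Observation ids are strings.
- Pairwise JSD uses the entropy identity JSD = H(M) − (H(P)+H(Q))/2,
  evaluated blockwise to bound memory; values are clipped at 0 to absorb
  round-off at identity.
- `cut_tree` guarantees exactly `N1` clusters and nested refinement
  across resolutions; domain renumbering by decreasing size breaks ties
  by smallest contained observation index.
- Problem sizes in the validation suite (100–150 observations per
  domain, 5–9 slices, 20-seed repetitions) keep every scenario exact
  while the full suite and the reproduction script each run in well
  under a minute of compute per scenario; the same code paths scale to
  thousands of observations, where the n×n distance matrix is the
  dominant cost (it is always materialized; no approximate-neighbor
  shortcuts).

## Known limitations

- Coordinates are planar Euclidean; no 3-D stacks, geodesic distances or
  image registration.  Slices are never aligned spatially — comparability
  comes solely from the shared cell-type vocabulary.
- Upstream cell typing / deconvolution is consumed, not performed; the
  `log_normalize` helper is provided for convenience only.
- No graph-community clustering (Leiden/Louvain), no post-hoc spatial
  smoothing of labels, no probabilistic/soft reference assignment.
- The adaptive domain-number rule is tuned for clearly separated domain
  structure; on gradual spatial gradients it will conservatively report
  fewer domains (often 1), and a manual `n_domains` is the intended
  recourse.
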