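# Methods

## Model

`sspyct` grows oblique predictive clustering trees from L labeled and U
unlabeled examples. Notation: features `X ∈ R^{(L+U)×D}` with the labeled
rows first, targets `Y ∈ R^{L×T}` (task-dependent encoding), clustering
weights `p ∈ R^{D+T}` assigning priorities to features and targets jointly.

At every node:

1. **Standardization.** Features are standardized to mean 0, sd 1 over the
   node's rows; targets over the node's labeled rows. The population
   standard-deviation convention is used throughout, matching the weighted
   variance `var(v, a) = mean(v², a) − mean(v, a)²` that defines the
   impurity. Zero-variance columns keep σ = 1 and map to zeros. Sparse
   feature matrices are scaled but not centered, preserving sparsity; all
   downstream computations (distances, variances, gradients) work directly
   on CSR matrices.
2. **Weight scaling.** Raw priorities (uniform over features; uniform over
   targets, or 0.75^depth for HMLC) are scaled so the feature block sums to
   `1 − ω` and the target block to `ω`.
3. **Split learning** with one of the two variants below.
4. **Acceptance.** The hard partition (hyperplane score ≥ 0, equivalently
   fuzzy membership ≥ 0.5; ties go to the positive child) is accepted iff
   each child receives at least `min_leaf_labeled` labeled examples and the
   size-weighted mean of the child impurities is at most
   `(1 − imp_reduction)` times the node impurity, both measured in the
   node's standardized space with all-ones membership weights. Rejected or
   failed splits immediately yield a leaf (no reseeded retries), keeping
   growth deterministic.
5. **Leaves** store the column-wise mean of the raw labeled targets. At
   prediction time rows are routed by each node's stored hyperplane and
   standardization; the leaf prototype is decoded per task (identity for
   regression, 0.5 threshold for BC and MLC/HMLC, argmax with lowest-index
   tie-break for MCC).

### SVM variant

Two-cluster k-means over the joint standardized (feature, target) space.
Initial centroids are two distinct labeled rows (random draws, up to 10
retries, then a deterministic scan; a node whose labeled rows coincide in
joint space is unsplittable). Unlabeled examples are masked out of the
target term of the distance (α = 0) and of centroid target updates; distance
ties are broken uniformly at random. A fully empty cluster is re-seeded from
a random labeled row (it has no assigned examples, so this cannot raise the
objective); a cluster left without labeled members keeps its previous target
part — while it has no labeled members that part does not enter the
objective, and updating only the feature part keeps the k-means objective
non-increasing. The final partition
is approximated on the features by an L1-regularized squared-hinge linear
SVM — solved by liblinear (`sklearn.svm.LinearSVC`, primal), which minimizes
exactly `‖w‖₁ + C Σ max(0, 1 − yₖ fₖ)²`. Cluster indicators are mapped to
±1 for the hinge: under the raw {0, 1} indicators the 0-cluster terms would
be constant and exert no force. liblinear also regularizes the intercept;
with per-split standardized features the bias is small and the effect is
negligible.

### Gradient variant

Fuzzy membership `s = σ(X_s w + b)`; group impurity
`imp(a, p) = Σ_k p_k var(X_{:,k}, a) + Σ_k p_{D+k} var(Y_{:,k}, a_{1..L})`;
fitness `f(w, b) = S·imp(s) + (L+U−S)·imp(1−s)` with `S = Σ s_i` — the size
factors steer the search toward balanced splits. The objective
`Σ_i sqrt(|w_i| + 1e−8) + C·f(w, b)` (a smoothed, differentiable
realization of the `‖w‖_{1/2}` penalty) is minimized with Adam from
`w ~ N(0, 1/D)`, `b = 0`. The gradient is analytic, via
`∂var(v,a)/∂a_i = ((v_i − mean)² − var)/Σa`, and is verified against central
finite differences in the test suite. The optimizer keeps the
best-objective iterate seen rather than the last one — Adam alone does not
guarantee descent, and returning the incumbent makes the final objective
never worse than the initial one at no extra cost.

### Supervision degree ω

`ω = 0` ignores targets entirely (unsupervised growth: permuting the
targets cannot change the tree structure); `ω = 1` ignores features in the
impurity, and the implementation drops the unlabeled rows at the root in
this case, making the fit bit-identical to a supervised fit on the labeled
rows alone — with literal ω = 1 weights the unlabeled rows would still leak
into standardization, tie-breaking and the SVM approximation. When
`omega="auto"`, ω is chosen from {0, 0.25, 0.5, 0.75, 1} by 3-fold
cross-validation over the labeled rows only; unlabeled rows join every
internal training fold, each fold is scored with the task's outer metric
(mean R² / F1 / weighted LRAP), and ties prefer the largest ω (more
supervision) since unlabeled structure can mislead.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `C` | 10 | strength of the data term vs the sparsity penalty |
| `opt_iters` | 100 | hyperplane-optimization iterations (both variants) |
| `clust_iters` | 10 | k-means rounds (SVM variant) |
| `adam_lr`, β₁, β₂, ε | 0.1, 0.9, 0.999, 1e−8 | Adam constants; the step size is the package's choice, exposed in `SplitConfig` |
| `min_leaf_labeled` | 1 | labeled examples required per leaf |
| `max_depth` | unlimited | depth cap |
| `imp_reduction` | 0.05 | split must remove ≥ 5% of node impurity |
| ensemble size | 50 | trees per bagging ensemble |

Bagging uses a **stratified bootstrap**: L draws with replacement from the
labeled rows plus U draws from the unlabeled rows, so every tree keeps at
least one labeled example and the labeled fraction of the training set.
Per-tree randomness comes from spawned RNG streams, with separate streams
for the bootstrap and for growth, so the labeled part of a bootstrap is
unchanged by the presence of unlabeled rows (this is what makes the ω = 1
equivalence hold for ensembles too).

## The impurity gate

The stopping rule compares the size-weighted mean of the child impurities
with the parent impurity (law of total variance: the split must genuinely
remove ≥ 5% of the node's impurity as between-child variance). The
alternative per-child rule — accept when *either* child alone is 5% below
the parent — was implemented and rejected: on targets statistically
independent of the features it accepts splits through sampling fluctuation
alone (a child's variance has sd ≈ √(2/m) around the parent's, and the
optimizer pushes one child low), after which acceptance chains and trees
grow to full depth. The weighted rule stops pure-noise growth at the root
while accepting every probe split on genuinely clustered data.

## Synthetic data

`gen_clustered` draws `n_clusters` Gaussian clusters with identity
covariance whose centers sit on a regular simplex with pairwise distance
`separation` (in within-cluster sd units), embedded in the first
`⌈(1 − noise_frac)·D⌉` coordinates; targets are deterministic per cluster
(class id for BC, one-hot for MCC, a fixed random half of the labels for
MLC, one anchor label plus its ancestors for HMLC, and a cluster-specific
affine response with sd-0.1 noise for STR/MTR). Cluster priors are uniform.
This is the cleanest structure satisfying the cluster assumption; it has
none of the nuisance structure of real QSAR or gene-function tables
(correlated features, heteroscedastic noise, imbalanced or overlapping
clusters, label noise), so passing tests demonstrate correctness of the
algorithms under the model's own assumption, not field performance.

Problem sizes used by the tests and the acceptance script are desk-scale
choices in line with the smaller benchmark tables of this literature:
separability and limit checks at n = 150–650 with D = 4–6; the pure-noise
stopping control at n = 2000, D = 5 (a 5-feature phoneme-scale table); the
semi-supervised-benefit check at n = 500 with L = 10 labeled and 150
held-out test rows, 20 seeds; the importance study at n = 400, D = 8
doubled to 16 by standard-normal noise columns, L = 250, 50-tree SVM-variant
ensembles (the faster of the two split learners, since this study fits a
thousand trees), 20 repeats.

## Numerical choices and degenerate inputs

- Distance/score ties: k-means assignment ties are uniform-random from the
  node's seeded stream; hyperplane routing sends a zero score to the
  positive child; MCC argmax ties take the lowest class index.
- Weighted variance with zero total weight is defined as 0 (empty fuzzy
  group), avoiding 0/0; computed variances are clipped at 0 against
  round-off.
- A hyperplane whose partition leaves a side empty, a one-sided clustering,
  or a node whose labeled rows coincide in joint space all yield "no
  split" → leaf. A dataset with a single labeled example yields a root
  leaf.
- Hierarchy depths: top-level labels have depth 1 (so their weight is
  0.75), the convention of the predictive-clustering literature; a DAG
  node's depth is the mean of its parents' depths plus one. Label weights
  are `0.75^depth`, used both as clustering priorities and as LRAP weights.
- LRAP rows without positive labels are skipped with a warning; F1 uses the
  zero-division-0 convention.
- Unseen class labels at prediction time raise; partially missing target
  cells in a CSV raise (a row must be fully labeled or fully unlabeled).
- All randomness flows from explicit `numpy` Generators derived from a
  single seed via `spawn`; no global RNG state is touched. Model JSON is
  written with sorted keys and `repr`-exact floats, so equal seeds give
  byte-identical files.

## Limitations

- The gradient variant is a non-convex local search; only incumbent descent
  is guaranteed, not a global optimum, and split quality depends on the
  single random initialization per node.
- The SVM variant requires ≥ 2 labeled examples per node; with liblinear's
  regularized intercept the solved objective differs microscopically from
  the stated one.
- No pruning, no missing-feature handling, no kernelized splits, no
  boosting; hierarchies must be DAGs reachable from top-level labels.
- Internal-CV ω selection refits the model `folds × |grid|` times, which
  dominates training cost for ensembles.
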