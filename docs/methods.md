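# Methods

This note documents the models, numerical choices, and open design decisions
behind `morphograph`. It is the companion to the API documentation: nothing
here is an empirical claim beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Problem setting

Given a specimen-by-trait table of continuous linear measurements
(morphometrics, mm) and integer scale counts (meristics / pholidosis), the
package asks whether the specimens fall into discrete morphological forms
(morphotypes) without using any taxonomic labels. Specimens are modeled as
nodes of a morphospace graph; morphotypes are communities of that graph.

## Preprocessing

Size and age are the dominant confounders in linear morphometrics, so every
morphometric trait `t` other than total length is transformed to the log
shape ratio `ln(t / TL)`; meristic counts become `ln(x + 1)` to homogenize
variances; each resulting column is centered and scaled to unit sample
variance (denominator N − 1) so all traits weigh equally in Euclidean
distances. Juveniles, adults and both sexes are pooled with no adjustment.

The total-length column itself is retained as `ln(TL)`: the shape ratio of
TL against itself is identically zero and cannot be standardized, while a
log size axis keeps body size available as a predictor — body size is a
recognized axis of ecological divergence in squamates and shows up in the
cluster diagnoses. This choice is the package's own; alternatives (dropping
TL entirely) are a one-line change upstream of everything else.

Missing values are a hard error by default (the intended workflow is a
complete matrix); constant columns abort standardization unless explicitly
dropped. All transforms are logged per trait in `CorrectedMatrix.correction_log`.

## Morphospace graph

Each specimen is connected to its `k` nearest neighbors (Euclidean distance
on the corrected matrix; ties broken toward the lower row index so results
are deterministic), and the directed adjacency is symmetrized by the
element-wise maximum with its transpose — an edge exists if either endpoint
selected the other. Default `k = 4`; `sweep_k` scores each candidate `k` in
3..10 by the mean and standard deviation of Louvain modularity and of the
community count over `n_replicates = 20` runs that differ only in the
seeded node-visit order (the one stochastic element downstream). `select_k`
takes the `k` with the highest mean modularity among those whose two SD
ranks both fall in the best tertile, falling back to the global modularity
maximum, with all ties resolved to the smallest `k`. The tertile rule is
one explicit instantiation of "maximal modularity with minimal spread";
the criteria themselves are standard, the arbitration is ours.

## Graph autoencoder

The encoder is a three-layer graph convolutional network with widths
(128, 64, d). Propagation uses the symmetric-normalized adjacency with
self-loops, `D̃^{-1/2}(A + I)D̃^{-1/2}`. Each hidden layer computes
propagate → linear map → LayerNorm (per node over features, ε = 1e-5,
learned gain and bias) → ELU (α = 1) → dropout (rate 0.15, inverted); the
final d-unit layer is a plain propagate → linear head, leaving the latent
space unconstrained. The decoder is the inner product
`Â = σ(Z Zᵀ)`, interpreted as edge probabilities.

Training minimizes a class-weighted binary cross-entropy over all
off-diagonal ordered pairs (each undirected pair counted twice, which
cancels in the mean; the diagonal is excluded because the target has no
self-loops). The positive-class weight defaults to the non-edge/edge ratio
("auto"; ≈ 97 for a 484-node, 1184-edge graph), the standard correction
for the extreme sparsity of k-NN graphs. Optimization is full-batch Adam
(β = 0.9/0.999, ε = 1e-8) for 1000 epochs with learning rate
0.008 · 0.5^⌊epoch/250⌋. Weights are Glorot-uniform from a seeded
generator; the GCN layers carry no bias (LayerNorm supplies the affine
terms). The loss is evaluated in the numerically stable softplus form;
reported probabilities are clamped away from {0, 1} by 1e-7 before any
logarithm. Everything is plain float64 numpy with hand-derived gradients
(the network is small and full-batch, so an autodiff framework would add
nothing); the gradient of the loss is verified against central finite
differences in the test suite, and training is bit-reproducible from the
config seed.

## Latent dimensionality

One model is trained per candidate `d` (1..P), with per-`d` seeds derived
deterministically from the master seed. Four metrics are recorded:

- **edge AUC** — ROC AUC of `Â` over all unordered pairs against the
  edge/non-edge labels (in-sample; rank/Mann–Whitney tie convention);
- **trustworthiness T(k)** — rank penalty for latent-space k-neighbors
  that were not input-space k-neighbors, with the same `k` as the graph;
- **ρ_dist** — Pearson correlation of the two pairwise-distance vectors
  (Mantel-style). This statistic can be negative, which is why it is the
  default; the formal (Székely) distance correlation, which cannot, is
  available via `method="szekely"`;
- **L_BCE** — the final training loss.

`select_dim` returns the smallest `d` with T(k) ≥ 0.9 whose relative loss
improvement over the previous `d` is below 1% (a stabilization point:
locally faithful, with no material gain from further dimensions); if no
`d` qualifies it falls back to the trustworthiness argmax with a warning.
Both thresholds are configurable; 0.9 is the conventional "high fidelity"
level for trustworthiness.

## Graph reconstruction and the probability threshold

The decoded `Â` must be sparsified before community detection. A model
trained with positive-class weight `w` is *not* calibrated at 0.5:
`σ(θ) = 0.5` corresponds to an unweighted edge posterior of roughly
`1/(1 + w)` (about 1% at w ≈ 97), so a fixed 0.5 cut keeps a large share
of the non-edge mass and buries the community structure in a near-complete
graph. There is also a geometric effect: with `G` groups and latent
dimension `d < G − 1`, not all group directions can be mutually obtuse, so
some between-group inner products necessarily sit at or above zero
(σ ≥ 0.5) however well the model fits.

The default (`tau="auto"`) therefore calibrates the threshold with Otsu's
criterion on the off-diagonal probabilities: the decoded values are
strongly bimodal (non-edge mode vs. reconstructed-edge mode), and Otsu
places the cut in the separating valley by maximizing between-class
variance, taking the midpoint of the maximizing plateau. This is
parameter-free and adapts to whatever positive weight was used. A fixed
numeric `tau` (including 0.5) remains available, as does a binary mode
that discards the surviving weights.

## Community detection and validation

Modularity is evaluated exactly in its weighted form,
`Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j)` with node strengths
`k_i` and total weight `m`, resolution fixed at 1. Louvain is implemented
directly: phase 1 repeatedly moves single nodes to the neighboring
community with the largest positive gain (seeded node-order shuffle;
ties keep the current community, then prefer the lowest community id;
improvement tolerance 1e-12), phase 2 collapses communities into
super-nodes whose self-loops carry the internal weight, and the phases
alternate to convergence. `best_of` reruns with derived seeds and keeps
the highest-Q partition; the tests use 10 restarts when comparing against
the exhaustive-search optimum on toy graphs, where single greedy passes
occasionally stop one move short.

Partitions are validated by (i) the conventional non-randomness threshold
Q ≥ 0.3 and (ii) normalized mutual information against the available
taxonomy, with natural-log entropies normalized by their arithmetic mean
(geometric-mean normalization behind a flag); a constant labeling scores
0 by convention. The species × cluster contingency table is exported for
inspection.

## SHAP diagnosis

A random forest (100 trees, scikit-learn defaults otherwise, seeded) is
trained to predict cluster membership from the corrected traits, and
path-dependent TreeSHAP — implemented in this package, with vector leaf
payoffs so all classes are decomposed in one traversal — attributes each
specimen's predicted class probabilities additively to traits. The
algorithm computes exact Shapley values of the tree-conditional
expectation game (splits outside the coalition are averaged over training
covers); the test suite checks it against brute-force Shapley enumeration
on small forests and verifies the additivity identity to 1e-6 for every
specimen and class. Cluster `c`'s diagnosis ranks traits by the mean
absolute contribution to class `c` over **all** specimens (a
`members_only` flag restricts to cluster members). Only within-cluster
rank order is surfaced: absolute magnitudes are diluted by the number of
classes and are not comparable across clusters.

## PCA / k-means baseline

The linear comparison arm: principal components retained to 95%
cumulative variance; k-means (k-means++ with 10 seeded restarts) scanned
over k = 2..15; the cluster count maximizing the mean silhouette wins
(singleton clusters score 0). The winning partition is scored by its
modularity on a symmetrized k-NN(4) graph built in the retained-component
space — no Louvain on this arm; the k-means labels are the partition —
and by NMI against the taxonomy. Silhouettes are computed in the
retained-component space, matching where the clustering happened.

## Variable-subset stability

For each subset size `s`, up to 1000 distinct trait subsets (exhaustive
when C(P, s) ≤ 1000) are re-run through correction, re-standardization
and the k-NN graph. The default mode clusters that graph directly with
Louvain — the subset perturbation probes the graph topology, and
retraining the autoencoder for every one of thousands of subsets buys
little beyond that at disproportionate cost — while `mode="full_gae"`
retrains per subset for users who want the literal full pipeline at
reduced replication. A k-means arm records the silhouette-selected
cluster count per subset. The stability verdict is the conjunction of:
modal community count at the largest size equals the full-data solution;
count SD non-increasing in trend across sizes (Spearman ρ ≤ 0, flat
profiles passing); and the share of subsets with Q ≥ 0.3 at least 0.9 at
every size. The 0.9 persistence level and the trend test are explicit
defaults for qualitative criteria ("low SD", "consistently high").

## Synthetic data

`simulate_morphotypes` generates trait tables with the structure the
pipeline assumes, so every stage is testable without any real dataset.
Total length is log-normal (median 450 mm, log-SD 0.25). Morphometric
trait `t` of a specimen in group `g` follows
`trait = a_{g,t} · TL^{b_{g,t}} · exp(ε)`, ε ~ N(0, noise_sd); with the
default isometric exponents `b = 1` the corrected log shape ratio is
exactly `ln a_{g,t} + ε`, so group structure is planted on the corrected
scale, where the pipeline operates. Meristic counts are Poisson (optional
negative binomial) with group means `exp(m_{g,t}) − 1` chosen so the
log1p-scale means carry the same planted offsets. Baseline trait levels
(shape ratios, count means) are fixed plausible values for a snake-like
dataset; they matter only through column scalings.

**Separation convention.** Group centers are drawn isotropically and
rescaled so the *minimum pairwise center distance* equals
`separation · noise_sd · √P` — separation counts center gaps in units of
the within-group RMS radius, the quantity that governs whether k-NN
neighborhoods mix clusters. (A per-coordinate convention, gap =
separation · noise_sd, would make clusters unrecoverable at any modest
separation in 21 dimensions, since within-group pair distances are
~noise_sd · √(2P).) Under this convention separation 0 plants nothing,
~1 gives heavy overlap, and ≥ 3 gives clouds whose k-NN graphs are nearly
group-pure. Default noise_sd = 0.08, a realistic residual SD for log
shape ratios.

The default end-to-end fixture (`default_porthidium_like`) is 484
specimens, 13 morphometric + 8 pholidosis traits, 12 equally sized groups
at separation 3 — the dimensions of a genus-scale dataset. What passing
tests on it show: the pipeline recovers planted, roughly equal, roughly
isotropically placed groups at moderate separation. What they do not
show: behavior under realistic trait covariance, unequal group sizes,
hierarchical or clinal variation, measurement error, or missing data —
the generator plants none of those.

## Problem sizes used in the shipped checks

The acceptance script runs the full pipeline (N = 484, d = 8, 1000
epochs) for five seeds. The separation-monotonicity check uses a reduced
configuration (160 specimens, 4 groups, d = 4, 300 epochs, five seeds per
separation level), and the variable-subset robustness check uses 48
specimens in 4 groups with up to 40 subsets per size — sizes at which the
properties under test are stable across sampling seeds, per the
module-level experiments in the test suite.

## Known limitations

- The inner-product decoder bounds how many mutually repelling groups fit
  in `d` dimensions; with many groups and small `d` the probability
  threshold, not the embedding, does the separating (see the calibration
  section). Very small `tau` values can reconnect everything.
- Path-dependent TreeSHAP is O(leaves · depth²) per sample and tree in
  pure Python; diagnosing thousands of specimens with deep forests is
  minutes, not seconds.
- The k-selection and stability procedures assume Louvain's seed-to-seed
  spread is the relevant instability; they do not bootstrap specimens.
- In-sample edge AUC (the default) is optimistic relative to held-out
  link prediction; the hold-out option is intentionally out of scope.
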