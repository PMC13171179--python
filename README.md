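# morphograph

Unsupervised detection of **morphotypes** — discrete morphological forms
within a species or lineage — from specimen-by-trait tables of linear
morphometrics and scale counts. Built for systematists working on
morphologically conservative or cryptic groups, where visual inspection
and linear multivariate statistics (PCA + k-means) flatten out the subtle,
non-linear structure that actually distinguishes forms.

## The method

Specimens are treated as nodes of a morphospace network rather than
independent points:

1. **Allometric correction** — morphometric traits become log shape
   ratios `ln(trait/TL)` against total length (TL itself enters as
   `ln TL`), scale counts become `ln(x+1)`, and every column is
   standardized to unit variance.
2. **k-NN graph** — each specimen links to its `k = 4` nearest neighbors
   (Euclidean); the adjacency is symmetrized by `max(M, Mᵀ)`. `k` can
   also be selected by a modularity-stability sweep over 3..10.
3. **Graph autoencoder** — a three-layer graph convolutional encoder
   (128, 64, d units; ELU, LayerNorm, 15% dropout) embeds specimens into
   a `d`-dimensional latent space; the inner-product decoder
   `Â = σ(ZZᵀ)` reconstructs edge probabilities. Training: weighted
   binary cross-entropy (positive-class weight = non-edge/edge ratio),
   1000 epochs of full-batch Adam, learning rate 0.008 halved every 250
   epochs. `d` is chosen where edge AUC, trustworthiness T(k), distance
   correlation ρ_dist and the final loss L_BCE stabilize.
4. **Community detection** — `Â` is thresholded (automatic Otsu
   calibration by default) into a weighted graph and partitioned by
   Louvain modularity maximization,
   `Q = (1/2m) Σᵢⱼ [Aᵢⱼ − kᵢkⱼ/2m] δ(cᵢ, cⱼ)`.
   Q ≥ 0.3 marks non-random community structure; normalized mutual
   information (NMI) scores agreement with the existing taxonomy.
5. **Diagnosis** — a 100-tree random forest predicts cluster membership
   and TreeSHAP ranks, per cluster, the traits that define it (top-10
   mean-|SHAP| ranking).
6. **Baseline & robustness** — a PCA (95% variance) + k-means
   (silhouette-selected k ∈ 2..15) comparison arm, and a stratified
   variable-subset stability analysis (up to 1000 random trait subsets
   per subset size).

A seeded synthetic-data generator (`simulate_morphotypes`) produces
planted-morphotype tables with group-specific allometries and count
distributions, so the whole pipeline is testable end to end.

## Worked example

Simulate 150 specimens in 4 planted groups and run the full pipeline:

```bash
morphograph simulate --out specimens.csv --n 150 --groups 4 \
    --separation 3 --seed 42
morphograph run-all specimens.csv --config specimens.csv.config.yaml \
    --outdir results --k 4 --latent-dim 4 --epochs 300 --seed 7
```

The run prints a stage summary (abridged):

```json
"graph":    {"n_nodes": 150, "n_edges": 447, "mean_degree": 5.96},
"train":    {"final_loss": 0.8337, "d": 4},
"cluster":  {"n_communities": 4, "Q": 0.7152},
"validate": {"Q": 0.7152, "nmi": 1.0},
"baseline": {"best_k": 4, "Q": 0.7496}
```

Reading this: the reconstructed morphospace graph partitions into **4
communities** — the planted morphotype count — with modularity
**Q = 0.715**, far above the 0.3 non-randomness threshold, and
**NMI = 1.0** against the simulated species labels (which here coincide
with the planted groups). `results/` also contains the corrected matrix,
edge list, latent embedding, per-cluster SHAP trait rankings
(`shap_diagnosis.csv` — e.g. cluster 0 is diagnosed first by head width
and ventral-scale count in this run), the PCA/k-means baseline report,
and a `manifest.json` with every parameter and sub-seed needed to
reproduce the run byte-for-byte.

Each stage is also a library call (`preprocess`, `knn_graph`, `train`,
`reconstruct_graph`, `louvain`, `validate`, `diagnose`,
`baseline_report`, `stability_run`) and a CLI subcommand; see
`morphograph --help` and `docs/methods.md` for the full model
description and design rationale.

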