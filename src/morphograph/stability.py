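"""Stratified combinatorial variable-subset stability analysis.

How robust is the detected morphotype count to the particular characters
measured?  For each subset size s, up to 1000 distinct trait subsets are
drawn (exhaustively when C(P, s) is small enough); each subset is re-run
through preprocessing and the k-NN graph, Louvain records the community
count and modularity, and the k-means/silhouette arm records its selected
cluster count.  The framework is called stable when the modal community
count at the largest sizes converges on the full-data solution, the spread
shrinks (or at least does not grow) with subset size, and the share of
subsets above the modularity threshold stays consistently high.

Re-training the autoencoder for every subset (mode="full_gae") is supported
at reduced replication; the default mode clusters the k-NN graph directly,
which is what the subset perturbation actually probes (the graph topology)
at a fraction of the cost.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .baseline import kmeans_scan, pca_scores
from .community import louvain, reconstruct_graph
from .gae import GAEConfig, train
from .graph import knn_graph
from .preprocessing import TraitTable, allometric_correct, standardize

logger = logging.getLogger(__name__)


class StabilityError(ValueError):
    pass


@dataclass
class StabilityReport:
    """Per-size distribution summaries of counts, k-means k, and Q."""

    table: pd.DataFrame
    q_threshold: float
    mode: str


def sample_subsets(
    n_traits: int,
    size: int,
    max_subsets: int = 1000,
    seed: int = 0,
) -> list[tuple[int, ...]]:
    """Distinct trait-index subsets of one size, exhaustive when possible.

    If C(n_traits, size) <= max_subsets every subset is returned (sorted);
    otherwise max_subsets distinct subsets are sampled uniformly without
    replacement, deterministically for a given seed.
    """
    if not 1 <= size <= n_traits:
        raise StabilityError(f"subset size {size} out of range [1, {n_traits}]")
    total = math.comb(n_traits, size)
    if total <= max_subsets:
        from itertools import combinations

        return sorted(combinations(range(n_traits), size))
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    while len(seen) < max_subsets:
        pick = tuple(sorted(rng.choice(n_traits, size=size, replace=False).tolist()))
        seen.add(pick)
    return sorted(seen)


def _subset_matrix(corrected_full: np.ndarray, names: list[str],
                   subset: tuple[int, ...]):
    sub = corrected_full[:, list(subset)]
    sub_names = [names[j] for j in subset]
    return standardize(sub, trait_names=sub_names, on_constant="drop")


def stability_run(
    table: TraitTable,
    sizes,
    mode: str = "graph",
    knn_k: int = 4,
    gae_config: GAEConfig | None = None,
    max_subsets: int = 1000,
    q_threshold: float = 0.3,
    include_kmeans: bool = True,
    kmeans_range=range(2, 16),
    seed: int = 0,
) -> StabilityReport:
    """Re-run the clustering arms over sampled trait subsets of each size.

    ``mode="graph"`` clusters the k-NN graph of each subset directly;
    ``mode="full_gae"`` additionally retrains the autoencoder per subset and
    clusters the reconstructed graph (use a reduced ``max_subsets``).
    Subsets whose corrected matrix degenerates (fewer than 2 usable columns
    or an edgeless graph) are skipped and counted.
    """
    if mode not in ("graph", "full_gae"):
        raise StabilityError(f"unknown mode {mode!r}")
    sizes = sorted(set(int(s) for s in sizes))
    if min(sizes) < 2 or max(sizes) > table.n_traits:
        raise StabilityError("sizes must lie within [2, P]")
    gae_config = gae_config or GAEConfig()
    corrected_full = allometric_correct(table)
    names = table.trait_names
    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        subsets = sample_subsets(table.n_traits, s, max_subsets=max_subsets,
                                 seed=int(rng.integers(2**31)))
        counts, qs, kmeans_ks = [], [], []
        skipped = 0
        for subset in subsets:
            sub_seed = int(rng.integers(2**31))
            try:
                cm = _subset_matrix(corrected_full, names, subset)
                if cm.X.shape[1] < 2:
                    raise StabilityError("fewer than 2 usable columns")
                g = knn_graph(cm, knn_k)
                if mode == "full_gae":
                    cfg = replace(gae_config, seed=sub_seed)
                    _, a_hat, _ = train(cm, g, cfg)
                    target = reconstruct_graph(a_hat, tau="auto")
                else:
                    target = g
                part = louvain(target, seed=sub_seed)
                counts.append(part.n_communities)
                qs.append(part.q)
                if include_kmeans:
                    scores, _, _ = pca_scores(cm, var_target=0.95)
                    best_k, _, _ = kmeans_scan(
                        scores, k_range=kmeans_range, n_init=10, seed=sub_seed,
                    )
                    kmeans_ks.append(best_k)
            except (ValueError, ArithmeticError) as exc:
                skipped += 1
                logger.warning("size %d subset %s skipped: %s", s, subset, exc)
        if not counts:
            raise StabilityError(f"every subset of size {s} degenerated")
        counts_a, qs_a = np.array(counts), np.array(qs)
        vals, freq = np.unique(counts_a, return_counts=True)
        rows.append({
            "size": s,
            "n_subsets": len(counts),
            "n_skipped": skipped,
            "mode_count": int(vals[np.argmax(freq)]),
            "mean_count": float(counts_a.mean()),
            "sd_count": float(counts_a.std(ddof=1)) if len(counts_a) > 1 else 0.0,
            "mode_kmeans_k": (int(np.bincount(kmeans_ks).argmax())
                              if kmeans_ks else np.nan),
            "mean_Q": float(qs_a.mean()),
            "sd_Q": float(qs_a.std(ddof=1)) if len(qs_a) > 1 else 0.0,
            "prop_Q_ge_threshold": float((qs_a >= q_threshold).mean()),
        })
    return StabilityReport(table=pd.DataFrame(rows), q_threshold=q_threshold,
                           mode=mode)


def assess_stability(
    report: StabilityReport,
    full_solution_count: int,
    q_threshold: float = 0.3,
    prop_threshold: float = 0.9,
) -> dict:
    """Three-criterion stability verdict.

    (i) convergence: the modal community count at the largest subset size
    equals the full-data solution; (ii) shrinking spread: the SD of the
    count is non-increasing in trend across sizes (Spearman rho <= 0, with
    a flat SD profile counting as non-increasing); (iii) persistence: the
    share of subsets with Q >= ``q_threshold`` is at least
    ``prop_threshold`` at every size.  The verdict is their conjunction.
    """
    t = report.table.sort_values("size")
    if len(t) == 0:
        raise StabilityError("empty stability report")
    converged = bool(t["mode_count"].iloc[-1] == full_solution_count)
    if len(t) > 1 and t["sd_count"].nunique() > 1:
        rho = spearmanr(t["size"], t["sd_count"]).statistic
        sd_trend_ok = bool(np.isnan(rho) or rho <= 0)
    else:
        sd_trend_ok = True
    prop_ok = bool((t["prop_Q_ge_threshold"] >= prop_threshold).all())
    return {
        "converged": converged,
        "sd_non_increasing": sd_trend_ok,
        "proportion_high": prop_ok,
        "stable": converged and sd_trend_ok and prop_ok,
    }
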