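"""Linear baseline: PCA to 95% variance, k-means with silhouette selection.

The comparison arm for the graph pipeline: project the corrected matrix onto
the principal components explaining a target share of variance, scan k-means
over a range of cluster counts (k-means++ with multiple restarts), pick the
cluster count maximizing the mean silhouette, then score that partition by
its modularity on a symmetrized k-NN graph built in the PCA coordinate space
and by NMI against the taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .community import modularity, nmi
from .graph import knn_graph
from .preprocessing import CorrectedMatrix


class BaselineError(ValueError):
    pass


def _as_array(X) -> np.ndarray:
    if isinstance(X, CorrectedMatrix):
        return X.X
    return np.asarray(X, dtype=float)


@dataclass
class BaselineReport:
    n_components_95: int
    best_k: int
    silhouette_by_k: dict[int, float]
    labels: np.ndarray
    Q_baseline: float
    nmi_vs_taxonomy: float
    explained_variance_ratio: np.ndarray


def pca_scores(X, var_target: float = 0.95):
    """Scores on the smallest component set reaching the variance target.

    Returns ``(scores, n_components, explained_variance_ratios)`` where the
    ratios cover the full decomposition (they sum to 1).
    """
    M = _as_array(X)
    if not 0 < var_target <= 1:
        raise BaselineError("var_target must lie in (0, 1]")
    pca = PCA(n_components=min(M.shape), svd_solver="full")
    scores_full = pca.fit_transform(M)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    if var_target == 1.0:
        m = int((ratios > 1e-12).sum())  # rank of the centered matrix
    else:
        m = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    return scores_full[:, :m], m, ratios


def silhouette(scores, labels) -> float:
    """Mean silhouette (b - a)/max(a, b); singleton clusters score 0."""
    M = _as_array(scores)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise BaselineError("silhouette requires at least 2 clusters")
    return float(silhouette_score(M, labels, metric="euclidean"))


def kmeans_scan(
    scores,
    k_range=range(2, 16),
    n_init: int = 10,
    seed: int = 0,
):
    """Silhouette-selected k-means over a range of cluster counts.

    Each k runs ``n_init`` seeded k-means++ starts (best inertia kept);
    ``best_k`` maximizes the silhouette, ties to the smallest k.  Returns
    ``(best_k, labels_of_best_k, silhouette_by_k)``.
    """
    M = _as_array(scores)
    ks = sorted(set(int(k) for k in k_range))
    if max(ks) >= M.shape[0]:
        raise BaselineError("max(k_range) must be < N")
    rng = np.random.default_rng(seed)
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                    random_state=int(rng.integers(2**31)))
        labels_by_k[k] = km.fit_predict(M)
        sil[k] = silhouette(M, labels_by_k[k])
    best_k = max(ks, key=lambda k: (sil[k], -k))
    return best_k, labels_by_k[best_k], sil


def baseline_report(
    X,
    taxonomy,
    var_target: float = 0.95,
    k_range=range(2, 16),
    n_init: int = 10,
    knn_k: int = 4,
    seed: int = 0,
) -> BaselineReport:
    """Full baseline: PCA -> k-means scan -> modularity on k-NN of scores -> NMI."""
    scores, m, ratios = pca_scores(X, var_target=var_target)
    best_k, labels, sil = kmeans_scan(scores, k_range=k_range, n_init=n_init,
                                      seed=seed)
    g = knn_graph(scores, knn_k)
    q = modularity(g, labels)
    taxonomy = np.asarray(taxonomy)
    if taxonomy.shape[0] != scores.shape[0]:
        raise BaselineError("taxonomy must cover all specimens")
    return BaselineReport(
        n_components_95=m,
        best_k=best_k,
        silhouette_by_k=sil,
        labels=labels,
        Q_baseline=q,
        nmi_vs_taxonomy=nmi(taxonomy, labels),
        explained_variance_ratio=ratios,
    )
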