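"""Morphospace graph construction and the k-selection sweep.

Each specimen is a node; directed edges point to its k nearest neighbors
under Euclidean distance in the corrected trait space, and the graph is made
undirected by the element-wise maximum of the adjacency with its transpose
(so an edge exists if either endpoint selected the other).  k is chosen by a
sweep over a range of values, scoring each by the mean and spread of Louvain
modularity and community count over replicated seeded runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .preprocessing import CorrectedMatrix


class GraphError(ValueError):
    pass


def _as_array(X) -> np.ndarray:
    if isinstance(X, CorrectedMatrix):
        return X.X
    return np.asarray(X, dtype=float)


@dataclass
class MorphoGraph:
    """Symmetric specimen graph with zero diagonal and positive weights."""

    adjacency: sp.csr_matrix
    binary: bool = True
    k_used: int | None = None

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency)
        if A.shape[0] != A.shape[1]:
            raise GraphError("adjacency must be square")
        if A.diagonal().any():
            raise GraphError("adjacency must have a zero diagonal")
        if (abs(A - A.T) > 1e-12).nnz:
            raise GraphError("adjacency must be symmetric")
        if A.nnz and A.data.min() <= 0:
            raise GraphError("edge weights must be > 0")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def degrees(self) -> np.ndarray:
        return np.asarray((self.adjacency != 0).sum(axis=1)).ravel()

    def edge_list(self) -> list[tuple[int, int, float]]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))


def knn_directed(X, k: int) -> sp.csr_matrix:
    """Directed k-NN adjacency: row i marks i's k nearest neighbors.

    Euclidean distance, self excluded; ties at the k-th distance are broken
    toward the lowest node index (stable sort), so the result is
    deterministic even on degenerate inputs with duplicate rows.
    """
    M = _as_array(X)
    n = M.shape[0]
    if not 1 <= k < n:
        raise GraphError(f"k must satisfy 1 <= k < N, got k={k}, N={n}")
    D = cdist(M, M)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    return sp.csr_matrix(
        (np.ones(n * k), (rows, order.ravel())), shape=(n, n)
    )


def symmetrize(directed: sp.spmatrix) -> MorphoGraph:
    """Undirect a 0/1 adjacency by the element-wise maximum with its transpose."""
    M = sp.csr_matrix(directed)
    if M.shape[0] != M.shape[1]:
        raise GraphError("adjacency must be square")
    if M.diagonal().any():
        raise GraphError("directed adjacency must have a zero diagonal")
    A = M.maximum(M.T)
    return MorphoGraph(adjacency=A, binary=True)


def knn_graph(X, k: int) -> MorphoGraph:
    """Symmetrized k-NN graph of the corrected matrix."""
    g = symmetrize(knn_directed(X, k))
    g.k_used = k
    return g


def graph_summary(G: MorphoGraph) -> dict:
    """Node/edge counts, mean degree 2E/N and density 2E/(N(N-1))."""
    n, e = G.n_nodes, G.n_edges
    if n < 2:
        raise GraphError("summary needs at least 2 nodes")
    return {
        "n_nodes": n,
        "n_edges": e,
        "mean_degree": 2 * e / n,
        "density": 2 * e / (n * (n - 1)),
    }


@dataclass
class KSweepReport:
    """Louvain stability summary per candidate k."""

    table: pd.DataFrame  # columns: k, mean_Q, sd_Q, mean_n_clusters, sd_n_clusters, n_replicates

    def __post_init__(self) -> None:
        t = self.table
        ks = t["k"].to_numpy()
        if len(ks) == 0:
            raise GraphError("empty k-sweep report")
        if len(np.unique(ks)) != len(ks) or not (np.diff(ks) > 0).all():
            raise GraphError("k values must be unique and ascending")
        if (t[["sd_Q", "sd_n_clusters"]].to_numpy() < 0).any():
            raise GraphError("standard deviations must be >= 0")


def sweep_k(
    X,
    k_range=range(3, 11),
    n_replicates: int = 20,
    seed: int = 0,
) -> KSweepReport:
    """Replicated Louvain runs on the k-NN graph for each candidate k.

    The replication randomness is the Louvain node-visit order (one distinct
    sub-seed per replicate), which is the stochastic element of the
    downstream pipeline this sweep is meant to stabilize.
    """
    from .community import WeightedGraph, louvain

    if n_replicates < 2:
        raise GraphError("need at least 2 replicates to estimate an SD")
    M = _as_array(X)
    ks = sorted(set(int(k) for k in k_range))
    if max(ks) >= M.shape[0]:
        raise GraphError("max(k_range) must be < N")
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        g = knn_graph(M, k)
        wg = WeightedGraph.from_adjacency(g.adjacency)
        qs, counts = [], []
        for _ in range(n_replicates):
            part = louvain(wg, seed=int(rng.integers(2**31)))
            qs.append(part.q)
            counts.append(part.n_communities)
        rows.append({
            "k": k,
            "mean_Q": float(np.mean(qs)),
            "sd_Q": float(np.std(qs, ddof=1)),
            "mean_n_clusters": float(np.mean(counts)),
            "sd_n_clusters": float(np.std(counts, ddof=1)),
            "n_replicates": n_replicates,
        })
    return KSweepReport(table=pd.DataFrame(rows))


def select_k(report: KSweepReport) -> int:
    """Pick the k that maximizes mean modularity among the most stable ks.

    Rule: rank sd_Q and sd_n_clusters ascending; candidates are the ks whose
    ranks both fall in the best tertile; among candidates take the highest
    mean_Q; if no k is in the best tertile of both SDs, fall back to the
    global mean_Q maximum.  All ties resolve to the smallest k.
    """
    from scipy.stats import rankdata

    t = report.table.sort_values("k").reset_index(drop=True)
    n = len(t)
    cutoff = int(np.ceil(n / 3))
    rank_q_sd = rankdata(t["sd_Q"], method="min")
    rank_n_sd = rankdata(t["sd_n_clusters"], method="min")
    stable = (rank_q_sd <= cutoff) & (rank_n_sd <= cutoff)
    candidates = t[stable] if stable.any() else t
    best_q = candidates["mean_Q"].max()
    winners = candidates[candidates["mean_Q"] >= best_q - 1e-12]
    return int(winners["k"].min())


def to_networkx(G: MorphoGraph, specimen_ids: list[str] | None = None):
    """Export to a networkx Graph (for GraphML serialization)."""
    import networkx as nx

    g = nx.from_scipy_sparse_array(G.adjacency)
    if specimen_ids is not None:
        nx.set_node_attributes(
            g, {i: s for i, s in enumerate(specimen_ids)}, "specimen_id"
        )
    return g
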