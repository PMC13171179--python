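"""Louvain community detection, modularity, and partition validation.

Morphotypes are operationalized as communities of the (weighted) specimen
graph under Newman-Girvan modularity

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] * delta(c_i, c_j)

with the weighted generalization (k_i = node strength, m = total edge
weight).  The Louvain heuristic greedily maximizes Q by repeated single-node
moves followed by community aggregation.  Partitions are validated by the
Q >= 0.3 non-randomness convention and by normalized mutual information
against the available taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp


class CommunityError(ValueError):
    pass


@dataclass
class WeightedGraph:
    """Undirected weighted graph: symmetric non-negative adjacency, zero diagonal."""

    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency, dtype=float)
        if A.shape[0] != A.shape[1]:
            raise CommunityError("adjacency must be square")
        if (abs(A - A.T) > 1e-9).nnz:
            raise CommunityError("adjacency must be symmetric")
        if A.diagonal().any():
            raise CommunityError("adjacency must have a zero diagonal")
        if A.nnz and A.data.min() < 0:
            raise CommunityError("weights must be non-negative")
        A.eliminate_zeros()
        self.adjacency = A

    @classmethod
    def from_adjacency(cls, A) -> "WeightedGraph":
        if sp.issparse(A):
            return cls(adjacency=sp.csr_matrix(A))
        return cls(adjacency=sp.csr_matrix(np.asarray(A, dtype=float)))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def total_weight(self) -> float:
        """m = half the sum of all weights."""
        return float(self.adjacency.sum()) / 2.0


@dataclass
class Partition:
    """Community labels (consecutive ints from 0) with their modularity."""

    labels: np.ndarray
    q: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise CommunityError("labels must be consecutive integers from 0")
        if not -1.0 - 1e-9 <= self.q <= 1.0 + 1e-9:
            raise CommunityError(f"modularity out of range: {self.q}")

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class ValidationReport:
    q: float
    q_threshold_passed: bool
    nmi_vs_taxonomy: float
    contingency: pd.DataFrame  # species x cluster counts


def _as_graph(G) -> WeightedGraph:
    if isinstance(G, WeightedGraph):
        return G
    if hasattr(G, "adjacency"):
        return WeightedGraph.from_adjacency(G.adjacency)
    return WeightedGraph.from_adjacency(G)


def otsu_threshold(values: np.ndarray, bins: int = 512) -> float:
    """Otsu's between-class-variance threshold for a bimodal score set.

    Classic parameter-free binarization: choose the cut maximizing the
    between-class variance of the two resulting score populations.  Used to
    calibrate the edge-probability threshold, because a model trained with a
    positive-class weight w is not calibrated at 0.5 — sigma(theta) = 0.5
    corresponds to an unweighted edge posterior of ~1/(1+w).
    """
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist / hist.sum()
    cum_w = np.cumsum(w)
    cum_mu = np.cumsum(w * centers)
    mu_total = cum_mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between_var = (mu_total * cum_w - cum_mu) ** 2 / (cum_w * (1 - cum_w))
    between_var[~np.isfinite(between_var)] = -np.inf
    # the criterion is flat across an empty valley: take the plateau midpoint
    best = between_var.max()
    plateau = np.flatnonzero(between_var >= best - 1e-12 * max(abs(best), 1.0))
    return float(centers[plateau].mean())


def reconstruct_graph(A_hat, tau: float | str = "auto",
                      mode: str = "weighted") -> WeightedGraph:
    """Sparsify a decoded edge-probability matrix into an undirected graph.

    Entries below the threshold are removed and the diagonal is zeroed.  In
    weighted mode surviving entries keep their probabilities as weights, in
    binary mode they become 1.  ``tau="auto"`` (default) calibrates the
    threshold with Otsu's criterion on the off-diagonal probabilities, which
    places the cut in the valley between the non-edge and edge probability
    modes regardless of the positive-class weight the model was trained
    with; a numeric ``tau`` in [0, 1) applies a fixed cut instead.
    """
    A = np.array(getattr(A_hat, "A_hat", A_hat), dtype=float)
    if tau == "auto":
        n = A.shape[0]
        tau = otsu_threshold(A[~np.eye(n, dtype=bool)])
    elif not 0 <= tau < 1:
        raise CommunityError("tau must lie in [0, 1)")
    if mode not in ("weighted", "binary"):
        raise CommunityError(f"unknown mode {mode!r}")
    np.fill_diagonal(A, 0.0)
    A[A < tau] = 0.0
    if mode == "binary":
        A[A > 0] = 1.0
    g = WeightedGraph.from_adjacency(A)
    if g.total_weight <= 0:
        raise CommunityError(
            f"thresholding at tau={tau} removed every edge (m = 0)"
        )
    return g


def modularity(G, labels) -> float:
    """Evaluate Q exactly for a given community assignment."""
    g = _as_graph(G)
    labels = np.asarray(labels)
    if labels.shape[0] != g.n_nodes:
        raise CommunityError("labels must cover all nodes")
    m = g.total_weight
    if m <= 0:
        raise CommunityError("modularity undefined for a graph with m = 0")
    _, lab = np.unique(labels, return_inverse=True)
    n_comm = lab.max() + 1
    strengths = g.strengths
    coo = g.adjacency.tocoo()
    same = lab[coo.row] == lab[coo.col]
    internal = np.zeros(n_comm)
    np.add.at(internal, lab[coo.row[same]], coo.data[same])  # ordered-pair sums
    sigma_tot = np.zeros(n_comm)
    np.add.at(sigma_tot, lab, strengths)
    return float((internal / (2 * m) - (sigma_tot / (2 * m)) ** 2).sum())


def louvain(G, seed: int = 0, best_of: int = 1, tol: float = 1e-12) -> Partition:
    """Two-phase Louvain modularity maximization.

    Phase 1 repeatedly moves single nodes to the neighboring community with
    the largest positive modularity gain (node order shuffled by ``seed``;
    ties keep the current community, otherwise the lowest community id).
    Phase 2 aggregates communities into super-nodes whose self-loops carry
    the internal weight.  Phases alternate until no move improves Q by more
    than ``tol``.  ``best_of > 1`` reruns with distinct sub-seeds and keeps
    the highest-Q partition.
    """
    g = _as_graph(G)
    if g.total_weight <= 0:
        raise CommunityError("Louvain requires a graph with m > 0")
    if best_of > 1:
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(best_of):
            part = louvain(g, seed=int(rng.integers(2**31)), best_of=1, tol=tol)
            if best is None or part.q > best.q:
                best = part
        return best

    rng = np.random.default_rng(seed)
    n0 = g.n_nodes
    # current level graph: neighbor dict (j -> weight, j != i), self-loop
    # weights (ordered-pair internal sums), node strengths incl. self-loops
    A = g.adjacency.tolil()
    neighbors = [
        {j: w for j, w in zip(rows, data)}
        for rows, data in zip(A.rows, A.data)
    ]
    self_w = np.zeros(n0)
    node_of = np.arange(n0)  # original node -> current-level node
    two_m = float(g.adjacency.sum())

    while True:
        n = len(neighbors)
        strengths = np.array(
            [sum(nb.values()) + self_w[i] for i, nb in enumerate(neighbors)]
        )
        comm = np.arange(n)
        sigma_tot = strengths.copy()
        order = rng.permutation(n)
        improved_level = False
        moved = True
        while moved:
            moved = False
            for i in order:
                ci = comm[i]
                ki = strengths[i]
                # weight from i to each neighboring community (self excluded)
                w_comm: dict[int, float] = {}
                for j, w in neighbors[i].items():
                    w_comm[comm[j]] = w_comm.get(comm[j], 0.0) + w
                sigma_tot[ci] -= ki
                base_gain = (
                    w_comm.get(ci, 0.0) / two_m * 2
                    - 2 * sigma_tot[ci] * ki / (two_m**2)
                )
                best_c, best_gain = ci, base_gain
                for c, w in w_comm.items():
                    if c == ci:
                        continue
                    gain = w / two_m * 2 - 2 * sigma_tot[c] * ki / (two_m**2)
                    if gain > best_gain + tol or (
                        abs(gain - best_gain) <= tol and best_c != ci and c < best_c
                    ):
                        best_c, best_gain = c, gain
                sigma_tot[best_c] += ki
                if best_c != ci:
                    comm[i] = best_c
                    moved = True
                    improved_level = True
        if not improved_level:
            break
        # phase 2: aggregate communities into super-nodes
        uniq, new_id = np.unique(comm, return_inverse=True)
        n_new = len(uniq)
        new_self = np.zeros(n_new)
        new_nb: list[dict[int, float]] = [dict() for _ in range(n_new)]
        for i, nb in enumerate(neighbors):
            ci = new_id[i]
            new_self[ci] += self_w[i]
            for j, w in nb.items():
                cj = new_id[j]
                if ci == cj:
                    new_self[ci] += w  # ordered pairs: counted from both ends
                else:
                    new_nb[ci][cj] = new_nb[ci].get(cj, 0.0) + w
        neighbors, self_w = new_nb, new_self
        node_of = new_id[node_of]
        if n_new == n:
            break

    _, labels = np.unique(node_of, return_inverse=True)
    # relabel by first appearance for a deterministic, order-stable output
    seen: dict[int, int] = {}
    out = np.empty_like(labels)
    for idx, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[idx] = seen[lab]
    return Partition(labels=out, q=modularity(g, out))


def nmi(labels_a, labels_b, average: str = "arithmetic") -> float:
    """Normalized mutual information between two labelings.

    Natural-log Shannon entropies; MI is normalized by the arithmetic mean
    of the two entropies (``average="geometric"`` switches to the sqrt
    convention).  If either labeling is constant (zero entropy) the score is
    0 by convention.  Invariant to label permutations.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape[0] != b.shape[0]:
        raise CommunityError("labelings must have equal length")
    if a.shape[0] == 0:
        raise CommunityError("labelings must be non-empty")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n = a.shape[0]
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1.0)
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    h_a = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
    h_b = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
    if h_a <= 0 or h_b <= 0:
        return 0.0
    nz = pij > 0
    mi = float(np.sum(pij[nz] * (np.log(pij[nz]) - np.log(np.outer(pi, pj)[nz]))))
    if average == "arithmetic":
        denom = (h_a + h_b) / 2
    elif average == "geometric":
        denom = float(np.sqrt(h_a * h_b))
    else:
        raise CommunityError(f"unknown NMI normalization {average!r}")
    return float(min(max(mi / denom, 0.0), 1.0))


def validate(G, partition: Partition, taxonomy) -> ValidationReport:
    """Structural (Q >= 0.3) and taxonomic (NMI) validation of a partition."""
    g = _as_graph(G)
    taxonomy = np.asarray(taxonomy)
    if taxonomy.shape[0] != g.n_nodes:
        raise CommunityError("taxonomy must cover all nodes")
    species = pd.Series(taxonomy, name="species")
    clusters = pd.Series(partition.labels, name="cluster")
    cont = pd.crosstab(species, clusters)
    return ValidationReport(
        q=partition.q,
        q_threshold_passed=bool(partition.q >= 0.3),
        nmi_vs_taxonomy=nmi(taxonomy, partition.labels),
        contingency=cont,
    )
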