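"""Modularity, Louvain, NMI, graph reconstruction, and validation."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import normalized_mutual_info_score

from morphograph.community import (
    CommunityError,
    Partition,
    WeightedGraph,
    louvain,
    modularity,
    nmi,
    otsu_threshold,
    reconstruct_graph,
    validate,
)


def _graph(A):
    return WeightedGraph.from_adjacency(np.asarray(A, dtype=float))


def two_triangles():
    A = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[a, b] = A[b, a] = 1
    return _graph(A)


def _set_partitions(n):
    """All partitions of range(n) via restricted-growth strings."""
    def rec(i, groups):
        if i == n:
            yield [list(g) for g in groups]
            return
        for g in groups:
            g.append(i)
            yield from rec(i + 1, groups)
            g.pop()
        groups.append([i])
        yield from rec(i + 1, groups)
        groups.pop()

    yield from rec(0, [])


def _brute_force_max_modularity(A):
    """Independent oracle: exhaustive search with a dense Q evaluation."""
    n = A.shape[0]
    k = A.sum(axis=1)
    two_m = A.sum()
    B = A - np.outer(k, k) / two_m
    best = -np.inf
    for parts in _set_partitions(n):
        q = sum(B[np.ix_(p, p)].sum() for p in parts) / two_m
        best = max(best, q)
    return best


class TestModularity:
    def test_all_in_one_partition_is_zero(self, rng):
        A = (rng.random((8, 8)) < 0.5).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        if A.sum() == 0:
            A[0, 1] = A[1, 0] = 1
        assert modularity(_graph(A), np.zeros(8)) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles(self):
        q = modularity(two_triangles(), [0, 0, 0, 1, 1, 1])
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_singletons_on_a_triangle(self):
        A = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        q = modularity(_graph(A), [0, 1, 2])
        assert q == pytest.approx(-1 / 3, abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_to_relabeling_and_weight_scale(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        A = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.6), 1)
        A = A + A.T
        if A.sum() == 0:
            A[0, 1] = A[1, 0] = 0.5
        labels = rng.integers(0, 3, size=n)
        q = modularity(_graph(A), labels)
        # relabel communities
        perm = rng.permutation(3)
        assert modularity(_graph(A), perm[labels]) == pytest.approx(q, abs=1e-12)
        # scale all weights
        assert modularity(_graph(A * 7.3), labels) == pytest.approx(q, abs=1e-12)

    def test_empty_graph_fatal(self):
        with pytest.raises(CommunityError):
            modularity(_graph(np.zeros((3, 3))), [0, 0, 0])


class TestLouvain:
    def test_two_cliques_joined_by_one_edge(self):
        A = np.zeros((10, 10))
        for block in (range(5), range(5, 10)):
            for a, b in itertools.combinations(block, 2):
                A[a, b] = A[b, a] = 1
        A[4, 5] = A[5, 4] = 1
        for seed in range(5):
            part = louvain(_graph(A), seed=seed)
            assert part.n_communities == 2
            assert len(set(part.labels[:5])) == 1
            assert len(set(part.labels[5:])) == 1

    def test_matches_exhaustive_optimum_on_small_graphs(self, rng):
        """Heuristic vs oracle on random graphs with N <= 8 (>= 95% exact)."""
        hits = 0
        trials = 50
        for t in range(trials):
            n = int(rng.integers(4, 9))
            A = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
            A = A + A.T
            if A.sum() == 0:
                A[0, 1] = A[1, 0] = 1
            part = louvain(_graph(A), seed=t, best_of=10)
            if part.q >= _brute_force_max_modularity(A) - 1e-9:
                hits += 1
        assert hits >= int(0.95 * trials)

    def test_q_is_self_consistent_and_nonnegative_vs_trivial(self):
        g = two_triangles()
        part = louvain(g, seed=1)
        assert part.q == pytest.approx(modularity(g, part.labels), abs=1e-12)
        assert part.q >= 0.0

    def test_identical_seed_identical_partition(self, rng):
        A = np.triu((rng.random((20, 20)) < 0.3).astype(float), 1)
        A = A + A.T
        a = louvain(_graph(A), seed=11)
        b = louvain(_graph(A), seed=11)
        assert np.array_equal(a.labels, b.labels) and a.q == b.q

    def test_labels_are_consecutive_from_zero(self, rng):
        A = np.triu((rng.random((15, 15)) < 0.4).astype(float), 1)
        A = A + A.T
        part = louvain(_graph(A), seed=2)
        assert set(part.labels) == set(range(part.n_communities))


class TestNmi:
    def test_identical_labelings(self):
        assert nmi([0, 0, 1, 1, 2], [5, 5, 7, 7, 9]) == pytest.approx(1.0)

    def test_constant_labeling_scores_zero(self):
        assert nmi([0, 0, 0, 0], [0, 1, 0, 1]) == 0.0

    def test_independent_two_by_two_design(self):
        assert nmi([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_sklearn_cross_check(self, rng):
        for _ in range(20):
            a = rng.integers(0, 4, size=50)
            b = rng.integers(0, 3, size=50)
            ours = nmi(a, b)
            assert ours == pytest.approx(nmi(b, a), abs=1e-12)
            theirs = normalized_mutual_info_score(a, b,
                                                  average_method="arithmetic")
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_length_mismatch_fatal(self):
        with pytest.raises(CommunityError):
            nmi([0, 1], [0, 1, 2])


class TestReconstructGraph:
    def test_tau_zero_keeps_complete_graph(self):
        A_hat = np.full((4, 4), 0.3)
        g = reconstruct_graph(A_hat, tau=0.0)
        assert g.adjacency.nnz == 12  # all off-diagonal pairs
        assert g.adjacency.diagonal().sum() == 0

    def test_fixed_tau_drops_weak_edges(self):
        A_hat = np.array([
            [0.0, 0.9, 0.4],
            [0.9, 0.0, 0.4],
            [0.4, 0.4, 0.0],
        ])
        g = reconstruct_graph(A_hat, tau=0.5)
        assert g.adjacency.nnz == 2
        assert g.adjacency[0, 1] == pytest.approx(0.9)

    def test_binary_mode_weights_are_unit(self):
        A_hat = np.array([
            [0.0, 0.9, 0.6],
            [0.9, 0.0, 0.2],
            [0.6, 0.2, 0.0],
        ])
        g = reconstruct_graph(A_hat, tau=0.5, mode="binary")
        assert set(g.adjacency.data) == {1.0}

    def test_all_edges_removed_fatal(self):
        with pytest.raises(CommunityError, match="m = 0"):
            reconstruct_graph(np.full((3, 3), 0.1), tau=0.9)

    def test_otsu_threshold_splits_bimodal_scores(self, rng):
        low = rng.normal(0.2, 0.03, size=500)
        high = rng.normal(0.85, 0.03, size=100)
        tau = otsu_threshold(np.clip(np.r_[low, high], 0, 1))
        assert 0.35 < tau < 0.7
        assert (low < tau).all() and (high > tau).all()

    def test_auto_tau_separates_probability_modes(self, rng):
        n = 30
        lab = np.repeat([0, 1], n // 2)
        same = lab[:, None] == lab[None, :]
        A_hat = np.where(same, 0.9, 0.35) + rng.normal(0, 0.01, (n, n))
        A_hat = np.clip((A_hat + A_hat.T) / 2, 0.01, 0.99)
        g = reconstruct_graph(A_hat, tau="auto")
        dense = g.adjacency.toarray()
        off = ~np.eye(n, dtype=bool)
        assert (dense[same & off] > 0).all()
        assert (dense[~same & off] == 0).all()


class TestValidate:
    def test_threshold_flag_and_contingency(self):
        g = two_triangles()
        part = louvain(g, seed=0)
        species = np.array(["x", "x", "y", "y", "y", "y"])
        rep = validate(g, part, species)
        assert rep.q_threshold_passed is (rep.q >= 0.3)
        assert rep.contingency.sum(axis=1).tolist() == [2, 4]

    def test_nmi_is_one_when_taxonomy_matches_partition(self):
        g = two_triangles()
        part = Partition(labels=np.array([0, 0, 0, 1, 1, 1]),
                         q=modularity(g, [0, 0, 0, 1, 1, 1]))
        rep = validate(g, part, ["a", "a", "a", "b", "b", "b"])
        assert rep.nmi_vs_taxonomy == pytest.approx(1.0)
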