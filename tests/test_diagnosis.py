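"""SHAP diagnosis: brute-force Shapley oracle, additivity, signal recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier

from morphograph.diagnosis import (
    DiagnosisError,
    cluster_trait_ranking,
    diagnose,
    fit_cluster_classifier,
    shap_decompose,
)
from morphograph.preprocessing import TraitTable, preprocess
from morphograph.treeshap import _normalized_leaf_values, forest_shap_values


def _expvalue(tree, values, x, S, node=0):
    """Tree-conditional expectation: follow x on S, average elsewhere."""
    t = tree.tree_
    if t.children_left[node] < 0:
        return values[node]
    d = t.feature[node]
    left, right = t.children_left[node], t.children_right[node]
    if d in S:
        nxt = left if x[d] <= t.threshold[node] else right
        return _expvalue(tree, values, x, S, nxt)
    wl = t.weighted_n_node_samples[left]
    wr = t.weighted_n_node_samples[right]
    return (wl * _expvalue(tree, values, x, S, left)
            + wr * _expvalue(tree, values, x, S, right)) / (wl + wr)


def _brute_shapley(tree, x, n_features):
    """Exhaustive Shapley values of the tree-conditional game."""
    values = _normalized_leaf_values(tree)
    phi = np.zeros((n_features, values.shape[1]))
    for i in range(n_features):
        others = [f for f in range(n_features) if f != i]
        for size in range(len(others) + 1):
            for S in itertools.combinations(others, size):
                w = (math.factorial(size)
                     * math.factorial(n_features - size - 1)
                     / math.factorial(n_features))
                phi[i] += w * (_expvalue(tree, values, x, set(S) | {i})
                               - _expvalue(tree, values, x, set(S)))
    return phi


class TestTreeShapOracle:
    def test_matches_exhaustive_shapley_enumeration(self, rng):
        """Polynomial algorithm vs brute force on <= 3-feature forests."""
        for trial in range(8):
            m = int(rng.integers(2, 4))
            X = rng.normal(size=(40, m))
            y = rng.integers(0, 3, size=40)
            forest = RandomForestClassifier(
                n_estimators=3, max_depth=int(rng.integers(1, 5)),
                random_state=trial,
            ).fit(X, y)
            xs = X[:3]
            contrib, _ = forest_shap_values(forest, xs)
            brute = np.mean(
                [np.stack([_brute_shapley(est, x, m) for x in xs])
                 for est in forest.estimators_], axis=0)
            np.testing.assert_allclose(contrib, brute, atol=1e-10)

    def test_depth_one_stump_two_features(self, rng):
        X = np.array([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        y = np.array([0, 0, 1, 1])
        forest = RandomForestClassifier(n_estimators=1, max_depth=1,
                                        bootstrap=False,
                                        random_state=0).fit(X, y)
        contrib, base = forest_shap_values(forest, X)
        brute = np.stack([_brute_shapley(forest.estimators_[0], x, 2)
                          for x in X])
        np.testing.assert_allclose(contrib, brute, atol=1e-12)
        # the constant feature contributes nothing
        np.testing.assert_allclose(contrib[:, 1, :], 0.0, atol=1e-12)


class TestShapDecompose:
    def test_additivity_reproduces_predicted_probabilities(self, small_sim):
        cm = preprocess(small_sim.trait_table)
        forest = fit_cluster_classifier(cm, small_sim.planted_labels,
                                        n_estimators=15, seed=0)
        shap = shap_decompose(forest, cm)
        reconstructed = shap.base + shap.contributions.sum(axis=1)
        np.testing.assert_allclose(reconstructed, forest.predict_proba(cm.X),
                                   atol=1e-6)

    def test_constant_trait_has_zero_contribution(self, rng):
        X = rng.normal(size=(60, 3))
        X[:, 2] = 4.2
        y = (X[:, 0] > 0).astype(int)
        forest = fit_cluster_classifier(X, y, n_estimators=10, seed=1)
        shap = shap_decompose(forest, X)
        np.testing.assert_allclose(shap.contributions[:, 2, :], 0.0,
                                   atol=1e-12)

    def test_trait_set_mismatch_fatal(self, rng):
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        forest = fit_cluster_classifier(X, y, n_estimators=5, seed=0)
        with pytest.raises(DiagnosisError):
            shap_decompose(forest, X[:, :3])


class TestClusterClassifier:
    def test_separable_clusters_reach_perfect_training_accuracy(self, rng):
        X = rng.normal(size=(50, 3))
        y = (X[:, 1] > 0).astype(int)
        X[:, 1] += y * 10
        forest = fit_cluster_classifier(X, y, seed=0)
        assert forest.score(X, y) == 1.0

    def test_seeded_refit_is_deterministic(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        f1 = fit_cluster_classifier(X, y, n_estimators=10, seed=3)
        f2 = fit_cluster_classifier(X, y, n_estimators=10, seed=3)
        np.testing.assert_array_equal(f1.predict_proba(X), f2.predict_proba(X))

    def test_single_cluster_fatal(self, rng):
        with pytest.raises(DiagnosisError):
            fit_cluster_classifier(rng.normal(size=(20, 3)), np.zeros(20))

    def test_permuted_labels_score_near_chance_out_of_bag(self, rng):
        """Destroying the label-feature link leaves only chance accuracy."""
        X = rng.normal(size=(150, 5))
        y = np.repeat([0, 1, 2], 50)
        oob = []
        for rep in range(10):
            perm = rng.permutation(150)
            forest = clone(
                fit_cluster_classifier(X, y[perm], n_estimators=50, seed=rep)
            ).set_params(oob_score=True).fit(X, y[perm])
            oob.append(forest.oob_score_)
        assert abs(np.mean(oob) - 1 / 3) < 0.15


class TestRanking:
    def _single_trait_table(self, rng):
        """Two groups separated only by the ventral-scale count."""
        n = 120
        groups = np.repeat([0, 1], n // 2)
        tl = np.exp(rng.normal(6.0, 0.2, size=n))
        data = {
            "TL": tl,
            "HL": np.exp(-2.9 + np.log(tl) + rng.normal(0, 0.08, n)),
            "MBW": np.exp(-3.0 + np.log(tl) + rng.normal(0, 0.08, n)),
            "ven": rng.poisson(np.where(groups == 0, 120, 220)).astype(float),
            "SC": rng.poisson(30, n).astype(float),
        }
        values = pd.DataFrame(data, index=[f"s{i}" for i in range(n)])
        kinds = {"TL": "morphometric", "HL": "morphometric",
                 "MBW": "morphometric", "ven": "meristic", "SC": "meristic"}
        return TraitTable(values=values, trait_kind=kinds, tl_name="TL"), groups

    def test_planted_single_trait_ranks_first(self, rng):
        table, groups = self._single_trait_table(rng)
        cm = preprocess(table)
        diag = diagnose(cm, groups, n_estimators=30, seed=0)
        for cluster in (0, 1):
            assert diag.rankings[cluster][0][0] == "ven"

    def test_top_n_covers_all_traits_when_large(self, rng):
        table, groups = self._single_trait_table(rng)
        cm = preprocess(table)
        diag = diagnose(cm, groups, n_estimators=10, top_n=99, seed=0)
        assert all(len(r) == 5 for r in diag.rankings.values())

    def test_rankings_are_descending_and_bounded(self, small_sim):
        cm = preprocess(small_sim.trait_table)
        diag = diagnose(cm, small_sim.planted_labels, n_estimators=10,
                        top_n=10, seed=0)
        for ranking in diag.rankings.values():
            assert len(ranking) == 10
            vals = [v for _, v in ranking]
            assert vals == sorted(vals, reverse=True)
            assert min(vals) >= 0

    def test_members_only_restricts_the_averaging_set(self, rng):
        table, groups = self._single_trait_table(rng)
        cm = preprocess(table)
        forest = fit_cluster_classifier(cm, groups, n_estimators=10, seed=0)
        shap = shap_decompose(forest, cm)
        all_spec = cluster_trait_ranking(shap, groups, top_n=5)
        members = cluster_trait_ranking(shap, groups, top_n=5,
                                        members_only=True)
        assert all_spec.rankings[0][0][0] == members.rankings[0][0][0] == "ven"
        assert all_spec.rankings[0][0][1] != members.rankings[0][0][1]
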