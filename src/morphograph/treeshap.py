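"""Path-dependent TreeSHAP for scikit-learn decision-tree ensembles.

Computes exact Shapley values of the tree-conditional expectation game: the
value of a feature coalition S is the tree's expected output when features
in S follow the explained sample and the remaining splits are averaged over
the training cover (``weighted_n_node_samples``).  The polynomial-time
algorithm tracks, along each root-to-leaf path, the proportion of feature
subsets of every size that flow through the path, extending and unwinding
the path as splits are encountered (repeated features on a path are
unwound before re-extension, so each feature appears at most once).

Leaf payoffs may be vectors (class-probability rows), so one traversal per
sample yields contributions for every class at once.  Complexity is
O(leaves * depth^2) per sample and tree — entirely adequate for
specimen-scale morphometric tables.
"""

from __future__ import annotations

import numpy as np


def _extend(path: list[list[float]], pz: float, po: float, pi: int) -> list:
    """Append a split to the path and update subset-permutation weights."""
    new = [e.copy() for e in path]
    new.append([float(pi), pz, po, 1.0 if not path else 0.0])
    length = len(new)
    for i in range(length - 2, -1, -1):
        new[i + 1][3] += po * new[i][3] * (i + 1) / length
        new[i][3] = pz * new[i][3] * (length - 1 - i) / length
    return new


def _unwind(path: list[list[float]], i: int) -> list:
    """Remove path element i, undoing its weight contribution."""
    length = len(path)
    n = path[length - 1][3]
    out = [e.copy() for e in path[: length - 1]]
    o_i, z_i = path[i][2], path[i][1]
    for j in range(length - 2, -1, -1):
        if o_i != 0:
            tmp = out[j][3]
            out[j][3] = n * length / ((j + 1) * o_i)
            n = tmp - out[j][3] * z_i * (length - 1 - j) / length
        else:
            out[j][3] = out[j][3] * length / (z_i * (length - 1 - j))
    for j in range(i, length - 1):
        out[j][0], out[j][1], out[j][2] = path[j + 1][0], path[j + 1][1], path[j + 1][2]
    return out


def _unwound_sum(path: list[list[float]], i: int) -> float:
    return sum(e[3] for e in _unwind(path, i))


def tree_shap_values(
    children_left: np.ndarray,
    children_right: np.ndarray,
    feature: np.ndarray,
    threshold: np.ndarray,
    cover: np.ndarray,
    leaf_values: np.ndarray,
    x: np.ndarray,
) -> np.ndarray:
    """Per-feature Shapley contributions (n_features x n_outputs) for one sample."""
    n_features = x.shape[0]
    n_out = leaf_values.shape[1]
    phi = np.zeros((n_features, n_out))

    def recurse(node: int, path: list, pz: float, po: float, pi: int) -> None:
        path = _extend(path, pz, po, pi)
        if children_left[node] < 0:  # leaf
            v = leaf_values[node]
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                d = int(path[i][0])
                phi[d] += w * (path[i][2] - path[i][1]) * v
            return
        d = feature[node]
        if x[d] <= threshold[node]:
            hot, cold = children_left[node], children_right[node]
        else:
            hot, cold = children_right[node], children_left[node]
        iz = io = 1.0
        k = next((j for j in range(1, len(path)) if int(path[j][0]) == d), None)
        if k is not None:
            iz, io = path[k][1], path[k][2]
            path = _unwind(path, k)
        r = cover[node]
        recurse(hot, path, iz * cover[hot] / r, io, d)
        recurse(cold, path, iz * cover[cold] / r, 0.0, d)

    recurse(0, [], 1.0, 1.0, -1)
    return phi


def _normalized_leaf_values(tree) -> np.ndarray:
    """Leaf payoff rows; classifier leaves are normalized to probabilities."""
    values = tree.tree_.value.reshape(tree.tree_.node_count, -1).astype(float)
    sums = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        normed = np.where(sums > 0, values / sums, values)
    # regression trees (single output) are left as-is
    return normed if values.shape[1] > 1 else values


def tree_expected_value(tree) -> np.ndarray:
    """Cover-weighted mean leaf value: the empty-coalition payoff."""
    t = tree.tree_
    values = _normalized_leaf_values(tree)
    leaves = t.children_left < 0
    w = t.weighted_n_node_samples[leaves]
    return (values[leaves] * w[:, None]).sum(axis=0) / w.sum()


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SHAP decomposition of a fitted RandomForest over samples.

    Returns ``(contributions, base)`` where contributions has shape
    (n_samples, n_features, n_classes), base has shape (n_classes,), and
    ``base + contributions.sum(axis=1)`` equals ``forest.predict_proba(X)``
    (local accuracy / additivity).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    estimators = forest.estimators_
    n_out = estimators[0].tree_.value.shape[1] * estimators[0].tree_.value.shape[2]
    contrib = np.zeros((n, p, n_out))
    base = np.zeros(n_out)
    for est in estimators:
        t = est.tree_
        values = _normalized_leaf_values(est)
        base += tree_expected_value(est)
        for i in range(n):
            contrib[i] += tree_shap_values(
                t.children_left, t.children_right, t.feature, t.threshold,
                t.weighted_n_node_samples, values, X[i],
            )
    k = len(estimators)
    return contrib / k, base / k
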