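"""Morphological diagnosis of detected clusters via SHAP trait rankings.

A random forest is trained to predict cluster membership from the
standardized traits; TreeSHAP then decomposes every specimen's predicted
class probabilities into additive per-trait contributions, and each
cluster's diagnosis is the descending ranking of traits by mean absolute
contribution to that cluster's class.  Only the within-cluster rank order
is meaningful — absolute magnitudes are diluted by the number of classes in
the multiclass decomposition — so reports surface per-cluster rankings, not
cross-cluster magnitude comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .community import Partition
from .preprocessing import CorrectedMatrix
from .treeshap import forest_shap_values

logger = logging.getLogger(__name__)


class DiagnosisError(ValueError):
    pass


def _features(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, CorrectedMatrix):
        return X.X, X.trait_names
    M = np.asarray(X, dtype=float)
    return M, [f"trait_{j}" for j in range(M.shape[1])]


def _labels(labels) -> np.ndarray:
    if isinstance(labels, Partition):
        return labels.labels
    return np.asarray(labels, dtype=int)


@dataclass
class ShapContributions:
    """Per-specimen, per-trait, per-class additive contributions."""

    contributions: np.ndarray  # (n_specimens, n_traits, n_classes)
    base: np.ndarray  # (n_classes,)
    trait_names: list[str]
    classes: np.ndarray


@dataclass
class ShapDiagnosis:
    """Descending (trait, mean |SHAP|) ranking per cluster."""

    rankings: dict[int, list[tuple[str, float]]]
    n_estimators: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster": c, "rank": r + 1, "trait": t, "mean_abs_shap": v}
            for c, ranking in sorted(self.rankings.items())
            for r, (t, v) in enumerate(ranking)
        ]
        return pd.DataFrame(rows)


def fit_cluster_classifier(
    X,
    labels,
    n_estimators: int = 100,
    seed: int = 0,
) -> RandomForestClassifier:
    """Random forest on cluster labels (class-probability output).

    Clusters with fewer than 5 members trigger a warning — their SHAP
    rankings rest on very few examples; a single cluster is fatal.
    """
    M, _ = _features(X)
    y = _labels(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DiagnosisError("cannot diagnose a single cluster")
    if counts.min() < 2:
        raise DiagnosisError("every cluster needs at least 2 members")
    small = classes[counts < 5]
    if small.size:
        logger.warning("clusters with < 5 members: %s", small.tolist())
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(M, y)
    logger.info("cluster classifier training accuracy: %.4f", forest.score(M, y))
    return forest


def shap_decompose(forest: RandomForestClassifier, X) -> ShapContributions:
    """Additive decomposition of predicted class probabilities.

    For every specimen and class, base value plus the per-trait
    contributions reproduces ``predict_proba`` (local accuracy).
    """
    M, names = _features(X)
    if M.shape[1] != forest.n_features_in_:
        raise DiagnosisError(
            f"trait-set mismatch: forest expects {forest.n_features_in_} "
            f"features, got {M.shape[1]}"
        )
    contrib, base = forest_shap_values(forest, M)
    return ShapContributions(
        contributions=contrib, base=base, trait_names=names,
        classes=forest.classes_,
    )


def cluster_trait_ranking(
    contributions: ShapContributions,
    labels,
    top_n: int = 10,
    members_only: bool = False,
) -> ShapDiagnosis:
    """Per-cluster trait importance: mean |contribution| to that cluster's class.

    The mean is taken over all specimens by default (``members_only=True``
    restricts it to the cluster's own members).  Rankings are descending;
    ties break alphabetically by trait name.
    """
    y = _labels(labels)
    C = contributions.contributions
    if C.shape[0] != y.shape[0]:
        raise DiagnosisError("contributions must cover all specimens")
    rankings: dict[int, list[tuple[str, float]]] = {}
    for ci, cls in enumerate(contributions.classes):
        rows = C[y == cls] if members_only else C
        importance = np.abs(rows[:, :, ci]).mean(axis=0)
        order = sorted(
            zip(contributions.trait_names, importance),
            key=lambda tv: (-tv[1], tv[0]),
        )
        rankings[int(cls)] = [(t, float(v)) for t, v in order[:top_n]]
    return ShapDiagnosis(rankings=rankings, n_estimators=0, seed=0)


def diagnose(
    X,
    labels,
    n_estimators: int = 100,
    top_n: int = 10,
    seed: int = 0,
    members_only: bool = False,
) -> ShapDiagnosis:
    """Fit forest, decompose, and rank in one call."""
    forest = fit_cluster_classifier(X, labels, n_estimators=n_estimators,
                                    seed=seed)
    contributions = shap_decompose(forest, X)
    out = cluster_trait_ranking(contributions, labels, top_n=top_n,
                                members_only=members_only)
    out.n_estimators = n_estimators
    out.seed = seed
    return out
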