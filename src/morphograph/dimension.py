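"""Latent-dimensionality evaluation and selection.

Each candidate dimensionality d gets one trained autoencoder, scored by four
complementary structural metrics: edge-reconstruction AUC (global fidelity),
trustworthiness T(k) (retention of input-space k-nearest neighborhoods in
the latent space), the Pearson correlation of pairwise distances between the
input and latent spaces (Mantel-style; can be negative), and the final
training loss L_BCE (convergence).  The selected d is the stabilization
point: the smallest d that is high-fidelity locally (T(k) at or above a
threshold) while further dimensions no longer buy a material loss reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.manifold import trustworthiness as _sk_trustworthiness
from sklearn.metrics import roc_auc_score

from .gae import GAEConfig, LatentEmbedding, train
from .preprocessing import CorrectedMatrix

logger = logging.getLogger(__name__)


class DimensionError(ValueError):
    pass


def _as_array(X) -> np.ndarray:
    if isinstance(X, CorrectedMatrix):
        return X.X
    if isinstance(X, LatentEmbedding):
        return X.Z
    return np.asarray(X, dtype=float)


@dataclass
class DimensionalityReport:
    """Per-d metric table: d, auc, trustworthiness, rho_dist, l_bce."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if ((t["auc"] < 0) | (t["auc"] > 1)).any():
            raise DimensionError("AUC out of [0, 1]")
        if ((t["trustworthiness"] < 0) | (t["trustworthiness"] > 1)).any():
            raise DimensionError("trustworthiness out of [0, 1]")
        if ((t["rho_dist"] < -1) | (t["rho_dist"] > 1)).any():
            raise DimensionError("rho_dist out of [-1, 1]")
        if (t["l_bce"] < 0).any():
            raise DimensionError("L_BCE must be >= 0")


def edge_auc(A_hat, G) -> float:
    """ROC AUC of reconstructed probabilities over unordered node pairs.

    Labels are edge / non-edge in the input graph; ties follow the
    Mann-Whitney rank convention (a constant reconstruction scores 0.5).
    """
    P = np.asarray(getattr(A_hat, "A_hat", A_hat), dtype=float)
    A = getattr(G, "adjacency", G)
    A = A.toarray() if hasattr(A, "toarray") else np.asarray(A)
    if P.shape != A.shape:
        raise DimensionError("reconstruction and graph shapes differ")
    iu = np.triu_indices(P.shape[0], k=1)
    labels = (A[iu] != 0).astype(int)
    if labels.min() == labels.max():
        raise DimensionError("AUC undefined: graph has no edges or no non-edges")
    scores = P[iu]
    if scores.min() == scores.max():
        return 0.5
    return float(roc_auc_score(labels, scores))


def trustworthiness(X, Z, k: int = 4) -> float:
    """T(k): penalized rank of latent k-neighbors absent from input k-neighborhoods.

    T(k) = 1 - 2/(Nk(2N-3k-1)) * sum_i sum_{j in U_i(k)} (r(i,j) - k) where
    U_i(k) holds the points in i's latent k-neighborhood but not its input
    k-neighborhood, and r(i,j) is j's input-space distance rank from i.
    Valid for k < N/2.
    """
    Xa, Za = _as_array(X), _as_array(Z)
    n = Xa.shape[0]
    if not 1 <= k < n / 2:
        raise DimensionError(f"trustworthiness requires 1 <= k < N/2, got k={k}")
    return float(_sk_trustworthiness(Xa, Za, n_neighbors=k))


def distance_corr(X, Z, method: str = "pearson") -> float:
    """Correlation between input-space and latent-space pairwise distances.

    ``method="pearson"`` (default) correlates the upper-triangle vectors of
    the two Euclidean distance matrices (Mantel-style, range [-1, 1]).
    ``method="szekely"`` computes the formal distance correlation instead
    (double-centered; non-negative by construction).
    """
    Xa, Za = _as_array(X), _as_array(Z)
    if Xa.shape[0] != Za.shape[0]:
        raise DimensionError("X and Z must have the same number of rows")
    if Xa.shape[0] < 3:
        raise DimensionError("need at least 3 points")
    if method == "pearson":
        dx, dz = pdist(Xa), pdist(Za)
        if dx.std() == 0 or dz.std() == 0:
            raise DimensionError("zero-variance distance vector")
        return float(np.corrcoef(dx, dz)[0, 1])
    if method == "szekely":
        return _szekely_dcor(Xa, Za)
    raise DimensionError(f"unknown method {method!r}")


def _szekely_dcor(X: np.ndarray, Z: np.ndarray) -> float:
    from scipy.spatial.distance import squareform

    def centered(M):
        D = squareform(pdist(M))
        return (D - D.mean(axis=0, keepdims=True)
                - D.mean(axis=1, keepdims=True) + D.mean())

    a, b = centered(X), centered(Z)
    dcov2 = (a * b).mean()
    dvar_x, dvar_z = (a * a).mean(), (b * b).mean()
    if dvar_x <= 0 or dvar_z <= 0:
        raise DimensionError("zero distance variance")
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_z)))


def evaluate_dims(
    X,
    G,
    d_range,
    config: GAEConfig | None = None,
    k: int = 4,
) -> DimensionalityReport:
    """Train one model per candidate d and record the four metrics.

    Per-d training seeds are derived deterministically from the config seed,
    so the whole report is reproducible from one master seed.
    """
    config = config or GAEConfig()
    ds = sorted(set(int(d) for d in d_range))
    if not ds or min(ds) < 1:
        raise DimensionError("d_range must contain integers >= 1")
    rows = []
    for d in ds:
        sub_seed = int(np.random.default_rng([config.seed, d]).integers(2**31))
        cfg = replace(config, d=d, seed=sub_seed)
        emb, a_hat, trace = train(X, G, cfg)
        rows.append({
            "d": d,
            "auc": edge_auc(a_hat, G),
            "trustworthiness": trustworthiness(X, emb, k=k),
            "rho_dist": distance_corr(X, emb),
            "l_bce": trace.final_loss,
        })
    return DimensionalityReport(table=pd.DataFrame(rows))


def select_dim(
    report: DimensionalityReport,
    t_threshold: float = 0.9,
    loss_tol: float = 0.01,
) -> int:
    """Pick the stabilization point of the metric curves.

    Returns the smallest d with trustworthiness >= ``t_threshold`` whose
    relative L_BCE improvement over the previous evaluated d is below
    ``loss_tol`` (the loss plateau).  The first evaluated d has no
    predecessor and qualifies on trustworthiness alone.  If no d qualifies,
    falls back to the trustworthiness argmax with a logged warning.
    Deterministic and invariant to row order.
    """
    t = report.table.sort_values("d").reset_index(drop=True)
    if len(t) < 2:
        if len(t) == 1:
            return int(t["d"].iloc[0])
        raise DimensionError("empty dimensionality report")
    prev_loss = np.r_[np.nan, t["l_bce"].to_numpy()[:-1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        improvement = (prev_loss - t["l_bce"].to_numpy()) / prev_loss
    plateau = np.isnan(improvement) | (improvement < loss_tol)
    ok = (t["trustworthiness"].to_numpy() >= t_threshold) & plateau
    if ok.any():
        return int(t["d"].iloc[int(np.argmax(ok))])
    logger.warning(
        "no latent dimensionality reached T(k) >= %.3g with a loss plateau; "
        "falling back to the trustworthiness maximum", t_threshold,
    )
    return int(t["d"].iloc[int(np.argmax(t["trustworthiness"].to_numpy()))])
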