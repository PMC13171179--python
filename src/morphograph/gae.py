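"""Graph convolutional autoencoder for specimen embedding.

The encoder is a three-layer GCN (128, 64, d units) over the symmetric-
normalized adjacency with self-loops, D^(-1/2)(A+I)D^(-1/2).  Hidden layers
apply propagate -> linear -> LayerNorm -> ELU -> dropout; the final d-unit
layer is a plain propagate -> linear head so the latent space is
unconstrained.  The decoder reconstructs edge probabilities by the inner
product Â = sigma(Z Zᵀ), and training minimizes a class-weighted binary
cross-entropy over all off-diagonal node pairs (non-edges vastly outnumber
edges in a sparse k-NN graph, hence the positive-class weight) with Adam
under a step-decayed learning rate.

The network is small enough (N ≈ 500, full batch) that the forward and
backward passes are written directly in numpy; training is bit-reproducible
given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .preprocessing import CorrectedMatrix

logger = logging.getLogger(__name__)


class GAEError(ValueError):
    pass


@dataclass
class GAEConfig:
    """Architecture and optimization hyperparameters.

    Defaults follow the training protocol the pipeline is built around:
    hidden widths (128, 64), 15% dropout between layers, 1000 epochs of
    full-batch Adam starting at lr 0.008 and halving every 250 epochs,
    positive-class weight set automatically to the non-edge/edge ratio.
    """

    d: int = 8
    hidden: tuple[int, int] = (128, 64)
    dropout: float = 0.15
    epochs: int = 1000
    lr0: float = 0.008
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 250
    seed: int = 0
    pos_weight: float | str = "auto"
    elu_alpha: float = 1.0
    ln_eps: float = 1e-5
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise GAEError("dropout must lie in [0, 1)")
        if self.d < 1:
            raise GAEError("latent dimensionality must be >= 1")
        if self.lr0 <= 0 or self.epochs < 1:
            raise GAEError("lr0 must be > 0 and epochs >= 1")
        if self.pos_weight != "auto" and float(self.pos_weight) <= 0:
            raise GAEError("pos_weight must be > 0 or 'auto'")

    def learning_rate(self, epoch: int) -> float:
        return self.lr0 * self.lr_decay_factor ** (epoch // self.lr_decay_every)


@dataclass
class LatentEmbedding:
    """N x d nodal representations produced by the encoder."""

    Z: np.ndarray
    config: GAEConfig | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if not np.isfinite(self.Z).all():
            raise GAEError("latent embedding contains non-finite entries")

    @property
    def d(self) -> int:
        return self.Z.shape[1]


@dataclass
class ReconstructedAdjacency:
    """Decoded edge-probability matrix, symmetric with entries in (0, 1)."""

    A_hat: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A_hat, dtype=float)
        if np.abs(A - A.T).max() > 1e-9:
            raise GAEError("reconstructed adjacency must be symmetric")
        if A.min() <= 0 or A.max() >= 1:
            raise GAEError("edge probabilities must lie strictly inside (0, 1)")
        self.A_hat = A


@dataclass
class TrainingTrace:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.loss[-1]


def _dense(A) -> np.ndarray:
    if sp.issparse(A):
        return A.toarray()
    return np.asarray(A, dtype=float)


def _as_features(X) -> np.ndarray:
    if isinstance(X, CorrectedMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def normalize_adjacency(A) -> np.ndarray:
    """Symmetric GCN propagation matrix D̃^(-1/2)(A+I)D̃^(-1/2)."""
    A = _dense(A)
    if A.shape[0] != A.shape[1]:
        raise GAEError("adjacency must be square")
    if np.abs(A - A.T).max() > 1e-9:
        raise GAEError("adjacency must be symmetric")
    if np.abs(np.diag(A)).max() > 0:
        raise GAEError("adjacency must have a zero diagonal")
    A_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    return A_tilde * np.outer(d_inv_sqrt, d_inv_sqrt)


def init_params(n_features: int, config: GAEConfig,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Seeded Glorot-uniform weights; LayerNorm gains 1, biases 0."""
    widths = [n_features, *config.hidden, config.d]
    params: dict[str, np.ndarray] = {}
    for layer in range(3):
        fan_in, fan_out = widths[layer], widths[layer + 1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        params[f"W{layer + 1}"] = rng.uniform(-limit, limit, (fan_in, fan_out))
        if layer < 2:
            params[f"gamma{layer + 1}"] = np.ones(fan_out)
            params[f"beta{layer + 1}"] = np.zeros(fan_out)
    return params


def _elu(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x > 0, x, alpha * np.expm1(x))


def gcn_forward(
    X,
    A_norm: np.ndarray,
    params: dict[str, np.ndarray],
    config: GAEConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[LatentEmbedding, dict]:
    """Run the encoder; returns Z and the cache needed for backprop.

    With ``training=False`` dropout is disabled and the pass is
    deterministic given the parameters.
    """
    H = _as_features(X)
    if H.shape[1] != params["W1"].shape[0]:
        raise GAEError(
            f"feature width {H.shape[1]} does not match W1 "
            f"({params['W1'].shape[0]})"
        )
    if training and config.dropout > 0 and rng is None:
        raise GAEError("training mode with dropout needs an rng")
    cache: dict = {"inputs": [], "S": [], "xhat": [], "inv_std": [], "L": [],
                   "E": [], "mask": []}
    for layer in (1, 2):
        W = params[f"W{layer}"]
        gamma, beta = params[f"gamma{layer}"], params[f"beta{layer}"]
        M = A_norm @ H
        S = M @ W
        mu = S.mean(axis=1, keepdims=True)
        var = S.var(axis=1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + config.ln_eps)
        xhat = (S - mu) * inv_std
        L = gamma * xhat + beta
        E = _elu(L, config.elu_alpha)
        if training and config.dropout > 0:
            mask = (rng.random(E.shape) >= config.dropout) / (1 - config.dropout)
        else:
            mask = np.ones_like(E)
        cache["inputs"].append(H)
        cache["S"].append(S)
        cache["xhat"].append(xhat)
        cache["inv_std"].append(inv_std)
        cache["L"].append(L)
        cache["E"].append(E)
        cache["mask"].append(mask)
        H = E * mask
    cache["inputs"].append(H)
    Z = A_norm @ H @ params["W3"]
    return LatentEmbedding(Z=Z, config=config), cache


def decode(Z) -> ReconstructedAdjacency:
    """Inner-product decoder: Â_ij = sigma(<z_i, z_j>)."""
    Zm = np.asarray(getattr(Z, "Z", Z), dtype=float)
    logits = Zm @ Zm.T
    A_hat = _sigmoid(logits)
    eps = 1e-12
    return ReconstructedAdjacency(A_hat=np.clip(A_hat, eps, 1 - eps))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def auto_pos_weight(A) -> float:
    """Non-edge / edge ratio over ordered off-diagonal pairs."""
    A = _dense(A)
    n = A.shape[0]
    n_pos = int((A != 0).sum())
    n_pairs = n * (n - 1)
    if n_pos == 0 or n_pos == n_pairs:
        raise GAEError("pos_weight undefined for empty or complete graphs")
    return (n_pairs - n_pos) / n_pos


def weighted_bce(A_hat, A, pos_weight: float = 1.0) -> float:
    """Mean class-weighted BCE over off-diagonal ordered pairs.

    Probabilities at exactly 0 or 1 are clamped to [1e-7, 1 - 1e-7] with a
    logged notice (the log would otherwise diverge).
    """
    P = np.asarray(getattr(A_hat, "A_hat", A_hat), dtype=float)
    T = _dense(A)
    if P.shape != T.shape:
        raise GAEError("shape mismatch between reconstruction and target")
    if pos_weight == "auto":
        pos_weight = auto_pos_weight(T)
    if pos_weight <= 0:
        raise GAEError("pos_weight must be > 0")
    eps = 1e-7
    if P.min() < eps or P.max() > 1 - eps:
        logger.warning("clamping reconstructed probabilities to [%g, %g]",
                       eps, 1 - eps)
        P = np.clip(P, eps, 1 - eps)
    n = P.shape[0]
    off = ~np.eye(n, dtype=bool)
    Tb = (T != 0).astype(float)
    terms = -(pos_weight * Tb * np.log(P) + (1 - Tb) * np.log1p(-P))
    return float(terms[off].mean())


def bce_grad_wrt_logits(Z: np.ndarray, A_bin: np.ndarray,
                        pos_weight: float) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. the decoder logits theta = Z Zᵀ.

    Uses the softplus form for numerical stability; identical to
    :func:`weighted_bce` away from the clamp region.
    """
    n = Z.shape[0]
    theta = Z @ Z.T
    off = ~np.eye(n, dtype=bool)
    sp_pos = np.logaddexp(0.0, theta)    # softplus(theta) = -log(1 - sigma)
    sp_neg = np.logaddexp(0.0, -theta)   # softplus(-theta) = -log(sigma)
    terms = pos_weight * A_bin * sp_neg + (1 - A_bin) * sp_pos
    count = n * (n - 1)
    loss = float(terms[off].sum() / count)
    s = _sigmoid(theta)
    d_theta = ((1 - A_bin) * s - pos_weight * A_bin * (1 - s)) * off / count
    return loss, d_theta


def bce_grad_wrt_z(Z: np.ndarray, A_bin: np.ndarray,
                   pos_weight: float) -> tuple[float, np.ndarray]:
    """Loss and its analytic gradient w.r.t. Z (d_theta is symmetric)."""
    loss, d_theta = bce_grad_wrt_logits(Z, A_bin, pos_weight)
    return loss, 2.0 * d_theta @ Z


def _backward(
    dZ: np.ndarray,
    A_norm: np.ndarray,
    params: dict[str, np.ndarray],
    config: GAEConfig,
    cache: dict,
) -> dict[str, np.ndarray]:
    grads: dict[str, np.ndarray] = {}
    H2 = cache["inputs"][2]
    M3 = A_norm @ H2
    grads["W3"] = M3.T @ dZ
    dH = A_norm @ (dZ @ params["W3"].T)
    for layer in (2, 1):
        i = layer - 1
        dE = dH * cache["mask"][i]
        L = cache["L"][i]
        elu_grad = np.where(L > 0, 1.0, _elu(L, config.elu_alpha) + config.elu_alpha)
        dL = dE * elu_grad
        xhat = cache["xhat"][i]
        grads[f"gamma{layer}"] = (dL * xhat).sum(axis=0)
        grads[f"beta{layer}"] = dL.sum(axis=0)
        dxhat = dL * params[f"gamma{layer}"]
        inv_std = cache["inv_std"][i]
        dS = inv_std * (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
        )
        M = A_norm @ cache["inputs"][i]
        grads[f"W{layer}"] = M.T @ dS
        if layer > 1:
            dH = A_norm @ (dS @ params[f"W{layer}"].T)
    return grads


def train(
    X,
    G,
    config: GAEConfig,
) -> tuple[LatentEmbedding, ReconstructedAdjacency, TrainingTrace]:
    """Full-batch Adam training of the autoencoder on one graph.

    Returns the inference-mode embedding of the final parameters, its
    decoded adjacency, and the per-epoch loss / learning-rate trace.
    Bitwise reproducible for a fixed config.
    """
    Xm = _as_features(X)
    A = _dense(getattr(G, "adjacency", G))
    if A.shape[0] != Xm.shape[0]:
        raise GAEError("graph and feature matrix disagree on specimen count")
    A_bin = (A != 0).astype(float)
    np.fill_diagonal(A_bin, 0.0)
    A_norm = normalize_adjacency(A_bin)
    pos_weight = (auto_pos_weight(A_bin) if config.pos_weight == "auto"
                  else float(config.pos_weight))

    rng = np.random.default_rng(config.seed)
    params = init_params(Xm.shape[1], config, rng)
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2 = config.adam_betas
    trace = TrainingTrace()

    for epoch in range(config.epochs):
        emb, cache = gcn_forward(Xm, A_norm, params, config, training=True,
                                 rng=rng)
        loss, dZ = bce_grad_wrt_z(emb.Z, A_bin, pos_weight)
        if not np.isfinite(loss):
            raise GAEError(f"non-finite training loss at epoch {epoch}")
        grads = _backward(dZ, A_norm, params, config, cache)
        lr = config.learning_rate(epoch)
        t = epoch + 1
        for k in params:
            m_state[k] = beta1 * m_state[k] + (1 - beta1) * grads[k]
            v_state[k] = beta2 * v_state[k] + (1 - beta2) * grads[k] ** 2
            m_hat = m_state[k] / (1 - beta1**t)
            v_hat = v_state[k] / (1 - beta2**t)
            params[k] = params[k] - lr * m_hat / (np.sqrt(v_hat) + config.adam_eps)
        trace.loss.append(loss)
        trace.lr.append(lr)

    emb, _ = gcn_forward(Xm, A_norm, params, config, training=False)
    emb = LatentEmbedding(Z=emb.Z, config=replace(config))
    return emb, decode(emb), trace
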