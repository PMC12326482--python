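"""Alternating optimisation: reweighted SGD on the network, closed-form
membership updates, and memory-bank centroid/pseudo-label refreshes.

One training epoch performs, in order:

1. recompute the surrogate reweighting coefficients at the current
   parameters (once per epoch by default, per batch optionally);
2. minibatch SGD steps on weights and biases, each batch drawing from both
   domains (balanced half source / half target);
3. after each batch (or each epoch), write the batch features back into the
   memory bank, reassign target pseudo-labels by cosine nearest centroid,
   and refresh the centroids as pooled class means;
4. update the possibilistic memberships in closed form v = exp(-D/2).

The loop stops when the relative change of the surrogate objective stays
below ``tol`` over a five-epoch window, or at ``max_epochs``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .adaptive_loss import SigmaNormSpec
from .memory_bank import MemoryBank, assign_pseudo_labels, init_bank, refresh_centroids, update_bank
from .network import (
    AutoencoderParams,
    class_probabilities,
    compute_coefficients,
    forward,
    init_params,
    surrogate_gradients,
    surrogate_objective,
    total_objective,
)
from .possibilistic import CentroidSet, membership_update, pairwise_sigma_distances

__all__ = [
    "DomainDataset",
    "TrainConfig",
    "TrainHistory",
    "DadpcModel",
    "fit",
    "predict",
    "converged",
]


@dataclass
class DomainDataset:
    """Feature matrix (samples x features) with optional integer class labels."""

    X: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if len(self.y) != self.X.shape[0]:
                raise ValueError("label length must match sample count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class TrainConfig:
    """Hyperparameters of the joint objective and its optimiser.

    ``lambda1``/``lambda2`` regularise weights/biases, ``lambda3`` weights
    the possibilistic clustering term; ``sigma``/``sigma1`` are the robust
    norm parameters (sigma defaults to 0.001); ``tau`` the sharpening
    temperature; ``lr`` the SGD step size.
    """

    lambda1: float = 1e-3
    lambda2: float = 1e-3
    lambda3: float = 1.0
    sigma: float = 1e-3
    sigma1: float = 1e-3
    tau: float = 0.5
    lr: float = 1e-3
    lr_decay: float = 0.995  # per-epoch multiplicative step-size decay
    warmup_epochs: int = 20  # reconstruction + source classifier only
    batch_size: int = 64
    max_epochs: int = 300
    tol: float = 1e-6
    seed: int = 0
    cluster_layer: str = "bottleneck"
    centroid_refresh: str = "batch"  # 'batch' | 'epoch'
    square_sigma_terms: bool = True
    reweight_cadence: str = "epoch"  # 'epoch' | 'batch'
    hidden_dims: tuple = (128, 16, 128)
    activation: str = "tanh"
    standardize: str = "source"  # z-score features: 'source' | 'pooled' | 'off'

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3"):
            v = getattr(self, name)
            if v != 0 and not (1e-4 <= v <= 1e5):
                raise ValueError(f"{name} must be 0 or within [1e-4, 1e5], got {v}")
        if self.sigma <= 0 or self.sigma1 <= 0:
            raise ValueError("sigma and sigma1 must be positive")
        if self.cluster_layer not in ("bottleneck", "output"):
            raise ValueError("cluster_layer must be 'bottleneck' or 'output'")
        if self.centroid_refresh not in ("batch", "epoch"):
            raise ValueError("centroid_refresh must be 'batch' or 'epoch'")
        if self.reweight_cadence not in ("batch", "epoch"):
            raise ValueError("reweight_cadence must be 'batch' or 'epoch'")

    @property
    def spec(self) -> SigmaNormSpec:
        return SigmaNormSpec(sigma=self.sigma, sigma1=self.sigma1)


@dataclass
class TrainHistory:
    surrogate: list = field(default_factory=list)
    objective: list = field(default_factory=list)
    pseudo_accuracy: list = field(default_factory=list)
    label_churn: list = field(default_factory=list)
    centroid_drift: list = field(default_factory=list)
    wall_time: list = field(default_factory=list)


@dataclass
class DadpcModel:
    """Trained model bundle: network, memory bank, raw-mean centroids and config."""

    params: AutoencoderParams
    bank: MemoryBank
    centroids: CentroidSet
    config: TrainConfig
    n_classes: int
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None


def _one_hot(y: np.ndarray, K: int) -> np.ndarray:
    out = np.zeros((len(y), K))
    out[np.arange(len(y)), y] = 1.0
    return out


def _raw_class_means(H: np.ndarray, labels: np.ndarray, K: int, prev: np.ndarray) -> np.ndarray:
    """Class means of (unnormalised) features; empty classes keep ``prev``."""
    C = prev.copy()
    for k in range(K):
        members = labels == k
        if members.any():
            C[k] = H[members].mean(axis=0)
    return C


def fit(source: DomainDataset, target: DomainDataset, config: TrainConfig | None = None):
    """Train the model on labeled source + unlabeled target features.

    Returns ``(model, bank, history)``. Source labels must be integer class
    indices 0..K-1; target labels, if present on the dataset, are used only
    to report pseudo-label accuracy in the history, never for training.
    """
    config = config or TrainConfig()
    if source.y is None:
        raise ValueError("source domain must be labeled")
    if source.d != target.d:
        raise ValueError("source and target feature dimensions differ")
    rng = np.random.default_rng(config.seed)
    K = int(source.y.max()) + 1
    spec = config.spec

    # balanced per-epoch resampling handles n_s != n_t; the base arrays are fixed
    Xs, ys, Xt = source.X, source.y, target.X
    ns, nt, d = Xs.shape[0], Xt.shape[0], source.d
    X = np.vstack([Xs, Xt])
    N = ns + nt
    if config.standardize == "source":
        feat_mean = Xs.mean(axis=0)
        feat_scale = np.maximum(Xs.std(axis=0), 1e-12)
    elif config.standardize == "pooled":
        feat_mean = X.mean(axis=0)
        feat_scale = np.maximum(X.std(axis=0), 1e-12)
    elif config.standardize == "off":
        feat_mean = np.zeros(d)
        feat_scale = np.ones(d)
    else:
        raise ValueError("standardize must be 'source', 'pooled' or 'off'")
    X = (X - feat_mean) / feat_scale
    src_index = np.arange(ns)
    tgt_index = np.arange(ns, N)
    Y_src = _one_hot(ys, K)
    domain_mask = np.zeros(N, dtype=bool)
    domain_mask[:ns] = True

    layer_dims = [d, *config.hidden_dims, d]
    params = init_params(layer_dims, K, activation=config.activation, seed=config.seed)

    states = forward(params, X)
    H_lat = states.layer(params, config.cluster_layer)
    counts = Y_src.sum(axis=0)
    if np.any(counts < 1):
        raise ValueError("every class needs at least one source sample")
    C_raw = (Y_src.T @ H_lat[src_index]) / counts[:, None]
    centroids = CentroidSet(C=C_raw, counts=counts.astype(int))

    # with lambda3 = 0 the possibilistic clustering term -- and with it the
    # pseudo-label pooling that feeds centroid refreshes -- is inactive;
    # centroids then stay estimated from labeled source features only
    adapt = config.lambda3 != 0
    labels0 = np.concatenate([ys, np.zeros(nt, dtype=int)])
    bank = init_bank(H_lat, centroids, labels0, domain_mask)
    pseudo = assign_pseudo_labels(bank)
    bank.labels[tgt_index] = pseudo
    if adapt:
        centroids = CentroidSet(
            C=_raw_class_means(H_lat, bank.labels, K, C_raw), counts=None
        )
    V = membership_update(pairwise_sigma_distances(H_lat, centroids.C, spec))

    history = TrainHistory()
    t0 = time.perf_counter()
    prev_pseudo = pseudo.copy()

    for epoch in range(config.max_epochs):
        # clustering joins the objective after the warm-up phase, in which
        # only reconstruction and source classification shape the features
        warm = epoch < config.warmup_epochs
        adapt_now = adapt and not warm
        lam = (config.lambda1, config.lambda2, 0.0 if warm else config.lambda3)
        lr = config.lr * config.lr_decay**epoch
        if adapt and epoch == config.warmup_epochs:
            # end of warm-up: re-seed centroids from source latent features
            states = forward(params, X)
            H_lat = states.layer(params, config.cluster_layer)
            C_src = _raw_class_means(H_lat[src_index], ys, K, centroids.C)
            centroids = CentroidSet(C=C_src, counts=None)
            update_bank(bank, H_lat, np.arange(N))
            bank.B[bank.n_samples :] = C_src / np.linalg.norm(C_src, axis=1, keepdims=True)
            pseudo = assign_pseudo_labels(bank)
            bank.labels[tgt_index] = pseudo
            centroids = CentroidSet(C=_raw_class_means(H_lat, bank.labels, K, C_src), counts=None)
            V = membership_update(pairwise_sigma_distances(H_lat, centroids.C, spec))
        coeffs = compute_coefficients(params, X, centroids, spec, config.cluster_layer)

        # balanced minibatches over both domains
        bs = min(config.batch_size, N)
        half = bs // 2
        src_perm = rng.permutation(src_index)
        tgt_perm = rng.permutation(tgt_index)
        n_batches = max(1, int(np.ceil(max(ns, nt) / max(half, 1))))
        for b in range(n_batches):
            take = lambda perm, n: perm[np.mod(np.arange(b * half, (b + 1) * half), n)]
            idx = np.concatenate([take(src_perm, ns), take(tgt_perm, nt)])
            idx = np.unique(idx)
            Xb = X[idx]
            in_src = idx < ns
            src_rows = np.where(in_src)[0]
            Yb = Y_src[idx[in_src]]
            Vb = V[idx]

            if config.reweight_cadence == "batch":
                coeffs = compute_coefficients(params, X, centroids, spec, config.cluster_layer)
            cb = _subset_coeffs(coeffs, idx)
            st = forward(params, Xb)
            g = surrogate_gradients(
                params, Xb, Yb, src_rows, Vb, centroids, cb, *lam,
                tau=config.tau, cluster_layer=config.cluster_layer, states=st,
            )
            for m in range(params.n_layers):
                params.weights[m] -= lr * g.dW[m]
                params.biases[m] -= lr * g.db[m]
            params.head_W -= lr * g.dhead_W
            params.head_b -= lr * g.dhead_b

            # bank refresh with the just-updated features of this batch
            st = forward(params, Xb)
            update_bank(bank, st.layer(params, config.cluster_layer), idx)
            if adapt_now and config.centroid_refresh == "batch":
                pseudo = assign_pseudo_labels(bank)
                bank.labels[tgt_index] = pseudo
                refresh_centroids(bank)

        # epoch-level refresh of bank, pseudo-labels, centroids, memberships
        states = forward(params, X)
        H_lat = states.layer(params, config.cluster_layer)
        update_bank(bank, H_lat, np.arange(N))
        if adapt_now:
            pseudo = assign_pseudo_labels(bank)
            bank.labels[tgt_index] = pseudo
            refresh_centroids(bank)
            C_new = _raw_class_means(H_lat, bank.labels, K, centroids.C)
        else:
            # source-only centroids; pseudo-labels tracked for reporting only
            C_src = _raw_class_means(H_lat[src_index], ys, K, centroids.C)
            norms = np.maximum(np.linalg.norm(C_src, axis=1, keepdims=True), 1e-300)
            bank.B[bank.n_samples :] = C_src / norms
            pseudo = assign_pseudo_labels(bank)
            C_new = C_src
        churn = float(np.mean(pseudo != prev_pseudo))
        prev_pseudo = pseudo.copy()
        drift = float(np.linalg.norm(C_new - centroids.C))
        centroids = CentroidSet(C=C_new, counts=np.bincount(bank.labels, minlength=K))
        V = membership_update(pairwise_sigma_distances(H_lat, centroids.C, spec))

        coeffs = compute_coefficients(params, X, centroids, spec, config.cluster_layer, states=states)
        sur = surrogate_objective(
            params, X, Y_src, src_index, V, centroids, coeffs, *lam,
            tau=config.tau, cluster_layer=config.cluster_layer,
        )
        obj = total_objective(
            params, X, Y_src, src_index, V, centroids, spec, *lam,
            tau=config.tau, cluster_layer=config.cluster_layer,
            square_sigma_terms=config.square_sigma_terms,
        )
        if not np.isfinite(sur) or not np.isfinite(obj):
            raise RuntimeError(
                f"non-finite objective at epoch {epoch}: surrogate={sur}, objective={obj}"
            )
        history.surrogate.append(float(sur))
        history.objective.append(float(obj))
        history.label_churn.append(churn)
        history.centroid_drift.append(drift)
        history.wall_time.append(time.perf_counter() - t0)
        if target.y is not None:
            history.pseudo_accuracy.append(float(np.mean(pseudo == target.y)))

        done, _ = converged(history, config.tol)
        if done:
            break

    model = DadpcModel(
        params=params, bank=bank, centroids=centroids, config=config, n_classes=K,
        feature_mean=feat_mean, feature_scale=feat_scale,
    )
    return model, bank, history


def _subset_coeffs(coeffs, idx):
    from .network import SurrogateCoefficients

    return SurrogateCoefficients(
        a=coeffs.a[idx], r_w=coeffs.r_w, r_b=coeffs.r_b, e=coeffs.e[idx]
    )


def predict(model: DadpcModel, X_new: np.ndarray):
    """Nearest-centroid classification of new samples.

    Labels come from cosine distance between the configured layer's features
    and the bank centroids; scores are a softmax over negative cosine
    distances (probability-like, rows sum to one).
    """
    if model.params is None:
        raise ValueError("model is not trained")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if model.feature_mean is not None:
        X_new = (X_new - model.feature_mean) / model.feature_scale
    states = forward(model.params, X_new)
    F = states.layer(model.params, model.config.cluster_layer)
    Fn = F / np.maximum(np.linalg.norm(F, axis=1, keepdims=True), 1e-300)
    C = model.bank.centroids
    Cn = C / np.linalg.norm(C, axis=1, keepdims=True)
    D = 1.0 - Fn @ Cn.T
    labels = np.argmin(D, axis=1)
    e = np.exp(-D + D.min(axis=1, keepdims=True))
    scores = e / e.sum(axis=1, keepdims=True)
    return labels, scores


def converged(history: TrainHistory | list, tol: float, window: int = 5):
    """Convergence decision: relative surrogate change below ``tol`` across
    a trailing window. Returns ``(decision, epoch_index)``."""
    trace = history.surrogate if isinstance(history, TrainHistory) else list(history)
    if len(trace) < 2:
        return False, -1
    lo = max(0, len(trace) - window)
    seg = trace[lo:]
    ref = max(1.0, abs(seg[0]))
    if (max(seg) - min(seg)) / ref < tol:
        return True, len(trace) - 1
    return False, -1
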