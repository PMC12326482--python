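"""Encoder-decoder network, source classifier head, and the joint objective.

The feature learner is an (M+1)-layer autoencoder: layers 1..M/2 encode the
input into a bottleneck H^(M/2) (the "deep features"), layers M/2+1..M
decode back to the input dimension, H^(M). Three loss terms are composed:

* J1 - robust reconstruction error ||H^(M) - X||_sigma(^2) over both domains,
* J2 - source cross-entropy on temperature-sharpened class probabilities
  from a K-logit affine head on the bottleneck, plus sigma-norm weight and
  l2 bias regularisers,
* J3 - the possibilistic clustering distribution distance on the bottleneck
  features (see :mod:`dadpc.possibilistic`).

Training minimises the iteratively-reweighted quadratic surrogate of this
objective; the surrogate's gradients are hand-coded backpropagation and are
verified against central finite differences in the test-suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adaptive_loss import SigmaNormSpec, reweight_coefficient
from .possibilistic import CentroidSet, dpc_objective, fuzzy_entropy_penalty

__all__ = [
    "AutoencoderParams",
    "HiddenStates",
    "SurrogateCoefficients",
    "init_params",
    "forward",
    "reconstruction_loss",
    "sharpen",
    "class_probabilities",
    "source_loss",
    "total_objective",
    "surrogate_objective",
    "surrogate_gradients",
    "compute_coefficients",
    "ParamGradients",
    "save_params",
    "load_params",
]

LOG_FLOOR = 1e-12

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a, h: 1.0 - h**2),
    "relu": (lambda a: np.maximum(a, 0.0), lambda a, h: (a > 0).astype(float)),
    "identity": (lambda a: a, lambda a, h: np.ones_like(a)),
}


@dataclass
class AutoencoderParams:
    """Weights W^(m), biases b^(m) (m = 1..M) plus the K-way classifier head.

    ``weights[m]`` maps layer dimension d_{m} -> d_{m+1} (stored as
    d_{m+1} x d_{m}); ``layer_dims`` = [d, d_1, ..., d_M] with d_M = d and
    the bottleneck at index M/2. The head is a K x d_{M/2} affine map on the
    bottleneck features.
    """

    weights: list
    biases: list
    layer_dims: list
    activation: str
    head_W: np.ndarray
    head_b: np.ndarray

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def bottleneck_index(self) -> int:
        return self.n_layers // 2

    def validate(self) -> None:
        M = self.n_layers
        if M % 2 != 0:
            raise ValueError("number of layers M must be even")
        if self.layer_dims[0] != self.layer_dims[-1]:
            raise ValueError("input and output dimensions must match")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        for arr in [*self.weights, *self.biases, self.head_W, self.head_b]:
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite parameter array")


def default_layer_dims(d: int) -> list:
    """Architecture template d-500-300-500-d (the configuration used for
    1024-dimensional projected EEG features is 1024-500-300-500-1024)."""
    return [d, 500, 300, 500, d]


def init_params(
    layer_dims,
    n_classes: int,
    activation: str = "tanh",
    seed: int = 0,
) -> AutoencoderParams:
    """Symmetric-uniform fan-in-scaled initialisation with a fixed seed."""
    rng = np.random.default_rng(seed)
    dims = list(layer_dims)
    weights, biases = [], []
    for m in range(len(dims) - 1):
        fan_in = dims[m]
        scale = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-scale, scale, size=(dims[m + 1], dims[m])))
        biases.append(np.zeros(dims[m + 1]))
    bneck = dims[len(dims) // 2] if (len(dims) - 1) % 2 == 0 else dims[-1]
    head_scale = 1.0 / np.sqrt(bneck)
    head_W = rng.uniform(-head_scale, head_scale, size=(n_classes, bneck))
    head_b = np.zeros(n_classes)
    params = AutoencoderParams(
        weights=weights,
        biases=biases,
        layer_dims=dims,
        activation=activation,
        head_W=head_W,
        head_b=head_b,
    )
    params.validate()
    return params


@dataclass
class HiddenStates:
    """Per-layer activations H^(m); ``H[0]`` is the input batch (rows = samples)."""

    H: list
    A: list  # pre-activations a^(m), m = 1..M (A[0] unused placeholder)

    @property
    def reconstruction(self) -> np.ndarray:
        return self.H[-1]

    def bottleneck(self, params: AutoencoderParams) -> np.ndarray:
        return self.H[params.bottleneck_index]

    def layer(self, params: AutoencoderParams, which: str) -> np.ndarray:
        if which == "bottleneck":
            return self.bottleneck(params)
        if which == "output":
            return self.reconstruction
        raise ValueError("cluster layer must be 'bottleneck' or 'output'")


def forward(params: AutoencoderParams, X: np.ndarray) -> HiddenStates:
    """Forward pass H^(m) = f(W^(m) H^(m-1) + b^(m)); rows of X are samples."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.layer_dims[0]:
        raise ValueError(
            f"input dim {X.shape[1]} does not match network input {params.layer_dims[0]}"
        )
    f, _ = _ACTIVATIONS[params.activation]
    H, A = [X], [None]
    cur = X
    for W, b in zip(params.weights, params.biases):
        a = cur @ W.T + b
        cur = f(a)
        H.append(cur)
        A.append(a)
    return HiddenStates(H=H, A=A)


def _group_sigma(z: float, sigma: float) -> float:
    return (1.0 + sigma) * z**2 / (z + sigma)


def _sample_sigma_norm(R: np.ndarray, sigma: float) -> float:
    z = np.linalg.norm(R, axis=1)
    return float(np.sum((1.0 + sigma) * z**2 / (z + sigma)))


def reconstruction_loss(
    states: HiddenStates,
    X: np.ndarray,
    spec: SigmaNormSpec,
    square: bool = True,
) -> float:
    """J1 = ||H^(M) - X||_sigma with per-sample residual groups, optionally
    squared (the literal joint-objective convention; ``square=False`` gives
    the plain robust-loss reading)."""
    R = states.reconstruction - np.atleast_2d(X)
    val = _sample_sigma_norm(R, spec.sigma)
    return val**2 if square else val


def sharpen(p: np.ndarray, tau: float) -> np.ndarray:
    """Temperature sharpening p~_k = p_k^(1/tau) / sum_e p_e^(1/tau).

    Row-wise over a matrix of probability rows; tau = 1 is the identity and
    tau -> 0 converges to one-hot at the argmax.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    p = np.atleast_2d(np.asarray(p, dtype=float))
    # work in log space for numerical safety at small tau
    logp = np.log(np.maximum(p, LOG_FLOOR)) / tau
    logp -= logp.max(axis=1, keepdims=True)
    q = np.exp(logp)
    out = q / q.sum(axis=1, keepdims=True)
    return out


def class_probabilities(params: AutoencoderParams, H_bottleneck: np.ndarray) -> np.ndarray:
    """Softmax class probabilities from the affine head on bottleneck features."""
    logits = H_bottleneck @ params.head_W.T + params.head_b
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _weight_penalty(params: AutoencoderParams, spec: SigmaNormSpec, square: bool) -> float:
    total = 0.0
    for W in [*params.weights, params.head_W]:
        v = _group_sigma(float(np.linalg.norm(W)), spec.sigma)
        total += v**2 if square else v
    return total


def _bias_penalty(params: AutoencoderParams) -> float:
    return float(
        sum(np.sum(b**2) for b in params.biases) + np.sum(params.head_b**2)
    )


def source_loss(
    params: AutoencoderParams,
    states: HiddenStates,
    Y_source: np.ndarray,
    source_index: np.ndarray,
    spec: SigmaNormSpec,
    lambda1: float,
    lambda2: float,
    tau: float = 0.5,
    square: bool = True,
) -> float:
    """J2: cross-entropy of sharpened source predictions plus regularisers.

    ``Y_source`` is one-hot for the rows selected by ``source_index``. The
    weight penalty is the (optionally squared) sigma-norm per layer; the
    bias penalty is a plain squared l2 norm.
    """
    Hb = states.bottleneck(params)[source_index]
    p = class_probabilities(params, Hb)
    p_sharp = sharpen(p, tau)
    ce = -float(np.sum(Y_source * np.log(np.maximum(p_sharp, LOG_FLOOR))))
    return ce + lambda1 * _weight_penalty(params, spec, square) + lambda2 * _bias_penalty(params)


def total_objective(
    params: AutoencoderParams,
    X: np.ndarray,
    Y_source: np.ndarray,
    source_index: np.ndarray,
    V: np.ndarray,
    centroids: CentroidSet,
    spec: SigmaNormSpec,
    lambda1: float,
    lambda2: float,
    lambda3: float,
    tau: float = 0.5,
    cluster_layer: str = "bottleneck",
    square_sigma_terms: bool = True,
) -> float:
    """The joint objective J = J1 + J2 + J3 evaluated at the current state."""
    states = forward(params, X)
    j1 = reconstruction_loss(states, X, spec, square=square_sigma_terms)
    j2 = source_loss(
        params, states, Y_source, source_index, spec, lambda1, lambda2, tau, square_sigma_terms
    )
    j3 = dpc_objective(states.layer(params, cluster_layer), centroids, V, spec, lambda3)
    if not np.isfinite(j1 + j2 + j3):
        raise FloatingPointError("non-finite joint objective")
    return float(j1 + j2 + j3)


# ---------------------------------------------------------------------------
# Iteratively-reweighted quadratic surrogate and its hand-coded gradients
# ---------------------------------------------------------------------------


@dataclass
class SurrogateCoefficients:
    """Frozen reweighting coefficients of the quadratic surrogate.

    a: per-sample reconstruction weights; r_w: per-layer weight-penalty
    multipliers (last entry is the classifier head); r_b: bias multipliers,
    identically one because the bias penalty is already quadratic; e: the
    N x K cluster-distance weights.
    """

    a: np.ndarray
    r_w: np.ndarray
    r_b: np.ndarray
    e: np.ndarray


def compute_coefficients(
    params: AutoencoderParams,
    X: np.ndarray,
    centroids: CentroidSet,
    spec: SigmaNormSpec,
    cluster_layer: str = "bottleneck",
    states: HiddenStates | None = None,
) -> SurrogateCoefficients:
    """Reweighting coefficients evaluated at the current parameters."""
    states = states or forward(params, X)
    R = states.reconstruction - np.atleast_2d(X)
    a = reweight_coefficient(np.linalg.norm(R, axis=1), spec.sigma)
    r_w = np.array(
        [reweight_coefficient(float(np.linalg.norm(W)), spec.sigma)
         for W in [*params.weights, params.head_W]]
    )
    r_b = np.ones(len(params.biases) + 1)
    Hc = states.layer(params, cluster_layer)
    dist = np.linalg.norm(Hc[:, None, :] - centroids.C[None, :, :], axis=2)
    e = reweight_coefficient(dist, spec.sigma)
    return SurrogateCoefficients(a=np.atleast_1d(a), r_w=r_w, r_b=r_b, e=e)


@dataclass
class ParamGradients:
    dW: list
    db: list
    dhead_W: np.ndarray
    dhead_b: np.ndarray

    def flatten(self) -> np.ndarray:
        parts = [g.ravel() for g in self.dW] + [g.ravel() for g in self.db]
        parts += [self.dhead_W.ravel(), self.dhead_b.ravel()]
        return np.concatenate(parts)


def surrogate_objective(
    params: AutoencoderParams,
    X: np.ndarray,
    Y_source: np.ndarray,
    source_index: np.ndarray,
    V: np.ndarray,
    centroids: CentroidSet,
    coeffs: SurrogateCoefficients,
    lambda1: float,
    lambda2: float,
    lambda3: float,
    tau: float = 0.5,
    cluster_layer: str = "bottleneck",
) -> float:
    """The reweighted quadratic surrogate of the joint objective.

    With the coefficients frozen every sigma-norm term becomes a weighted
    squared l2 term; the cross-entropy, bias penalty and fuzzy-entropy terms
    are carried over unchanged.
    """
    states = forward(params, X)
    R = states.reconstruction - np.atleast_2d(X)
    recon = float(np.sum(coeffs.a * np.sum(R**2, axis=1)))

    Hb = states.bottleneck(params)[source_index]
    p_sharp = sharpen(class_probabilities(params, Hb), tau)
    ce = -float(np.sum(Y_source * np.log(np.maximum(p_sharp, LOG_FLOOR))))

    wpen = sum(
        r * float(np.sum(W**2))
        for r, W in zip(coeffs.r_w, [*params.weights, params.head_W])
    )
    bpen = _bias_penalty(params)

    Hc = states.layer(params, cluster_layer)
    diff = Hc[:, None, :] - centroids.C[None, :, :]
    sq = np.sum(diff**2, axis=2)
    clus = float(np.sum(coeffs.e * V**2 * sq)) + fuzzy_entropy_penalty(V)

    return recon + ce + lambda1 * wpen + lambda2 * bpen + lambda3 * clus


def surrogate_gradients(
    params: AutoencoderParams,
    X: np.ndarray,
    Y_source: np.ndarray,
    source_index: np.ndarray,
    V: np.ndarray,
    centroids: CentroidSet,
    coeffs: SurrogateCoefficients,
    lambda1: float,
    lambda2: float,
    lambda3: float,
    tau: float = 0.5,
    cluster_layer: str = "bottleneck",
    states: HiddenStates | None = None,
) -> ParamGradients:
    """Backpropagated gradients of :func:`surrogate_objective`.

    The output-layer error signal is driven by the weighted reconstruction
    residual; at the clustering layer the possibilistic pull toward the
    centroids and (at the bottleneck) the classifier-head error join the
    backward pass; weight/bias penalties contribute their quadratic
    gradients directly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    states = states or forward(params, X)
    _, fprime = _ACTIVATIONS[params.activation]
    M = params.n_layers
    bidx = params.bottleneck_index
    cidx = bidx if cluster_layer == "bottleneck" else M

    # dL/dH^(m) accumulators
    G = [np.zeros_like(h) for h in states.H]
    R = states.reconstruction - X
    G[M] += 2.0 * coeffs.a[:, None] * R

    # possibilistic clustering pull at the clustering layer
    Hc = states.H[cidx]
    w = coeffs.e * V**2  # N x K
    G[cidx] += 2.0 * lambda3 * (w.sum(axis=1)[:, None] * Hc - w @ centroids.C)

    # classifier head on the bottleneck (source rows only); gradient of the
    # sharpened cross-entropy w.r.t. the logits is (p_sharp - q) / tau
    Hb = states.H[bidx][source_index]
    p_sharp = sharpen(class_probabilities(params, Hb), tau)
    dlogits = (p_sharp - Y_source) / tau
    dhead_W = dlogits.T @ Hb + 2.0 * lambda1 * coeffs.r_w[-1] * params.head_W
    dhead_b = dlogits.sum(axis=0) + 2.0 * lambda2 * params.head_b
    Gb = dlogits @ params.head_W
    np.add.at(G[bidx], source_index, Gb)

    dW = [None] * M
    db = [None] * M
    for m in range(M, 0, -1):
        delta = G[m] * fprime(states.A[m], states.H[m])
        dW[m - 1] = delta.T @ states.H[m - 1] + 2.0 * lambda1 * coeffs.r_w[m - 1] * params.weights[m - 1]
        db[m - 1] = delta.sum(axis=0) + 2.0 * lambda2 * params.biases[m - 1]
        G[m - 1] += delta @ params.weights[m - 1]

    return ParamGradients(dW=dW, db=db, dhead_W=dhead_W, dhead_b=dhead_b)


# ---------------------------------------------------------------------------
# Serialization: portable array container + JSON metadata sidecar
# ---------------------------------------------------------------------------


def save_params(params: AutoencoderParams, path: str, meta: dict | None = None) -> None:
    """Save parameters as an .npz container with a JSON metadata sidecar."""
    path = Path(path)
    arrays = {f"W{m}": W for m, W in enumerate(params.weights)}
    arrays.update({f"b{m}": b for m, b in enumerate(params.biases)})
    arrays["head_W"] = params.head_W
    arrays["head_b"] = params.head_b
    np.savez(path, **arrays)
    sidecar = {
        "layer_dims": list(map(int, params.layer_dims)),
        "activation": params.activation,
        "n_classes": int(params.head_W.shape[0]),
    }
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_params(path: str) -> AutoencoderParams:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        M = len(meta["layer_dims"]) - 1
        params = AutoencoderParams(
            weights=[data[f"W{m}"] for m in range(M)],
            biases=[data[f"b{m}"] for m in range(M)],
            layer_dims=meta["layer_dims"],
            activation=meta["activation"],
            head_W=data["head_W"],
            head_b=data["head_b"],
        )
    params.validate()
    return params
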