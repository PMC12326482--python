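"""Validation protocols, metrics, the label-noise sweep and the
mutual-information feature map.

Protocols follow the EEG transfer-learning conventions:

* CUCE - leave-one-subject-out, all sessions of the held-out subject are
  the target and all sessions of every other subject the source;
* CUSE - leave-one-subject-out on session 1 only;
* WUCE - within-subject: sessions 1-2 are the source, session 3 the target;
* CDCV - one dataset entirely source, another entirely target.

Accuracies are reported in percent as mean +/- standard deviation over
folds, with a pooled confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import SyntheticDataset, corrupt_labels
from .trainer import DomainDataset, TrainConfig, fit, predict

__all__ = [
    "ProtocolSpec",
    "ProtocolResult",
    "run_protocol",
    "noise_sweep",
    "mutual_info_map",
    "confusion",
]

_PROTOCOLS = ("CUCE", "CUSE", "WUCE", "CDCV")


@dataclass(frozen=True)
class ProtocolSpec:
    """Named validation protocol with optional per-session fold splitting
    for CUCE."""

    name: str
    per_session_folds: bool = False

    def __post_init__(self) -> None:
        if self.name.upper() not in _PROTOCOLS:
            raise ValueError(f"protocol must be one of {_PROTOCOLS}")
        object.__setattr__(self, "name", self.name.upper())

    def folds(self, dataset: SyntheticDataset, other: SyntheticDataset | None = None):
        """Yield (source_keys, target_keys, target_dataset) per fold."""
        subjects, sessions = dataset.subjects, dataset.sessions
        if self.name == "CUCE":
            for subj in subjects:
                src = [(s, e) for s in subjects if s != subj for e in sessions]
                if self.per_session_folds:
                    for e in sessions:
                        yield src, [(subj, e)], dataset
                else:
                    yield src, [(subj, e) for e in sessions], dataset
        elif self.name == "CUSE":
            first = sessions[0]
            for subj in subjects:
                src = [(s, first) for s in subjects if s != subj]
                yield src, [(subj, first)], dataset
        elif self.name == "WUCE":
            if len(sessions) < 3:
                raise ValueError("WUCE needs at least three sessions")
            for subj in subjects:
                missing = [e for e in sessions[:3] if (subj, e) not in dataset.X]
                if missing:
                    warnings.warn(f"subject {subj} missing sessions {missing}; fold skipped")
                    continue
                yield [(subj, sessions[0]), (subj, sessions[1])], [(subj, sessions[2])], dataset
        else:  # CDCV
            if other is None:
                raise ValueError("CDCV needs a second dataset as target")
            src = [(s, e) for s in subjects for e in sessions]
            tgt = [(s, e) for s in other.subjects for e in other.sessions]
            yield src, tgt, other


@dataclass
class ProtocolResult:
    fold_accuracies: list  # percent, one per fold
    mean: float
    std: float
    confusion: np.ndarray

    def __str__(self) -> str:
        return f"Pacc = {self.mean:.2f} +/- {self.std:.2f}% over {len(self.fold_accuracies)} folds"


def confusion(labels_true, labels_pred, K: int) -> np.ndarray:
    """K x K count matrix; entry (i, j) counts true class i predicted as j."""
    t = np.asarray(labels_true, dtype=int)
    p = np.asarray(labels_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if t.min() < 0 or t.max() >= K or p.min() < 0 or p.max() >= K:
        raise ValueError(f"labels outside 0..{K - 1}")
    from sklearn.metrics import confusion_matrix

    return confusion_matrix(t, p, labels=np.arange(K))


def run_protocol(
    dataset: SyntheticDataset,
    spec: ProtocolSpec,
    config: TrainConfig | None = None,
    other: SyntheticDataset | None = None,
) -> ProtocolResult:
    """Train/evaluate one fit per fold and aggregate Pacc and confusion."""
    config = config or TrainConfig()
    K = dataset.recipe.n_classes
    accs, cm = [], np.zeros((K, K), dtype=int)
    for src_keys, tgt_keys, tgt_ds in spec.folds(dataset, other):
        Xs, ys = dataset.pooled(src_keys)
        Xt, yt = tgt_ds.pooled(tgt_keys)
        model, _, _ = fit(DomainDataset(Xs, ys), DomainDataset(Xt), config)
        pred, _ = predict(model, Xt)
        accs.append(100.0 * float(np.mean(pred == yt)))
        cm += confusion(yt, pred, K)
    return ProtocolResult(
        fold_accuracies=accs,
        mean=float(np.mean(accs)),
        std=float(np.std(accs)),
        confusion=cm,
    )


def noise_sweep(
    source: DomainDataset,
    target: DomainDataset,
    etas=(0, 5, 10, 15, 20, 25),
    config: TrainConfig | None = None,
    seed: int = 0,
) -> dict:
    """Target accuracy (percent) after corrupting eta% of the source labels.

    Noise touches only the source; the target is used purely for
    evaluation. Returns ``{eta: accuracy}``.
    """
    config = config or TrainConfig()
    if target.y is None:
        raise ValueError("target labels are needed to score the sweep")
    out = {}
    for eta in etas:
        ys = corrupt_labels(source.y, eta, seed=seed + int(eta))
        model, _, _ = fit(DomainDataset(source.X, ys), DomainDataset(target.X), config)
        pred, _ = predict(model, target.X)
        out[eta] = 100.0 * float(np.mean(pred == target.y))
    return out


def mutual_info_map(X_t: np.ndarray, P_hat: np.ndarray, n_neighbors: int = 3, seed: int = 0) -> np.ndarray:
    """K x d mutual-information map between features and class predictions.

    Predictions are hardened to labels; for each class k the MI between
    every feature column and the binary indicator (label == k) is estimated
    with the k-NN mixed continuous-discrete estimator, then the whole
    matrix is min-max scaled to [0, 1]. Constant feature columns have MI 0.
    """
    from sklearn.feature_selection import mutual_info_classif

    X_t = np.atleast_2d(np.asarray(X_t, dtype=float))
    P_hat = np.atleast_2d(np.asarray(P_hat, dtype=float))
    if X_t.shape[0] != P_hat.shape[0]:
        raise ValueError("feature and prediction rows must align")
    labels = np.argmax(P_hat, axis=1)
    K = P_hat.shape[1]
    I = np.zeros((K, X_t.shape[1]))
    for k in range(K):
        ind = (labels == k).astype(int)
        if ind.min() == ind.max():  # class absent or universal: MI undefined -> 0
            continue
        I[k] = mutual_info_classif(
            X_t, ind, n_neighbors=n_neighbors, random_state=seed, discrete_features=False
        )
    lo, hi = I.min(), I.max()
    if hi > lo:
        I = (I - lo) / (hi - lo)
    return I
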