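"""Memory bank: L2-normalised features for all N samples plus K centroids.

The bank decouples pseudo-labelling from minibatch composition: features of
samples outside the current batch stay available for centroid refreshes.
Rows are stored directly (no momentum blending). Target pseudo-labels are
assigned by nearest centroid under cosine distance; centroids are refreshed
as class means over source true labels pooled with target pseudo-labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .possibilistic import CentroidSet

__all__ = [
    "MemoryBank",
    "init_bank",
    "update_bank",
    "assign_pseudo_labels",
    "refresh_centroids",
]


def _l2_normalize(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm feature row cannot be normalised")
    return X / norms


@dataclass
class MemoryBank:
    """(N + K) x d store: rows 0..N-1 sample features, rows N..N+K-1 centroids.

    ``labels`` holds source true labels and target pseudo-labels (class
    indices); ``domain_mask`` is True for source rows, whose labels are
    immutable after construction.
    """

    B: np.ndarray
    labels: np.ndarray
    domain_mask: np.ndarray
    n_samples: int
    n_clusters: int

    @property
    def features(self) -> np.ndarray:
        return self.B[: self.n_samples]

    @property
    def centroids(self) -> np.ndarray:
        return self.B[self.n_samples :]


def init_bank(H_all: np.ndarray, C0: CentroidSet, labels: np.ndarray, domain_mask: np.ndarray) -> MemoryBank:
    """Build the bank from latent features of all samples and initial
    (source-class-mean) centroids; every row is L2-normalised."""
    F = _l2_normalize(H_all)
    C = _l2_normalize(C0.C)
    labels = np.asarray(labels, dtype=int).copy()
    domain_mask = np.asarray(domain_mask, dtype=bool).copy()
    if len(labels) != F.shape[0] or len(domain_mask) != F.shape[0]:
        raise ValueError("labels/domain_mask length must match sample count")
    return MemoryBank(
        B=np.vstack([F, C]),
        labels=labels,
        domain_mask=domain_mask,
        n_samples=F.shape[0],
        n_clusters=C.shape[0],
    )


def update_bank(bank: MemoryBank, batch_features: np.ndarray, batch_indices: np.ndarray) -> MemoryBank:
    """Overwrite exactly the rows in ``batch_indices`` with the new
    normalised features; all other rows are untouched (no momentum)."""
    idx = np.asarray(batch_indices, dtype=int)
    if idx.size == 0:
        return bank
    if idx.min() < 0 or idx.max() >= bank.n_samples:
        raise IndexError("batch index outside sample rows")
    bank.B[idx] = _l2_normalize(batch_features)
    return bank


def _cosine_distances(F: np.ndarray, C: np.ndarray) -> np.ndarray:
    Fn = F / np.linalg.norm(F, axis=1, keepdims=True)
    Cn = C / np.linalg.norm(C, axis=1, keepdims=True)
    return 1.0 - Fn @ Cn.T


def assign_pseudo_labels(bank: MemoryBank) -> np.ndarray:
    """Pseudo-labels for target rows: argmin_k of cosine distance to the
    bank centroids; ties break to the lowest class index (argmin order)."""
    target = ~bank.domain_mask
    D = _cosine_distances(bank.features[target], bank.centroids)
    labels = np.argmin(D, axis=1)
    out = bank.labels.copy()
    out[target] = labels
    return out[target]


def refresh_centroids(bank: MemoryBank, pseudo_labels: np.ndarray | None = None) -> CentroidSet:
    """Class-mean centroids over source true labels pooled with target
    pseudo-labels, L2-normalised back into the bank.

    A class with no members keeps its previous centroid (with a warning)
    rather than producing NaN.
    """
    if pseudo_labels is not None:
        bank.labels[~bank.domain_mask] = np.asarray(pseudo_labels, dtype=int)
    F = bank.features
    K = bank.n_clusters
    C = bank.centroids.copy()
    counts = np.zeros(K, dtype=int)
    for k in range(K):
        members = bank.labels == k
        counts[k] = int(members.sum())
        if counts[k] == 0:
            warnings.warn(f"cluster {k} empty during centroid refresh; keeping previous centroid")
            continue
        mean = F[members].mean(axis=0)
        norm = np.linalg.norm(mean)
        if norm == 0:
            warnings.warn(f"cluster {k} mean degenerate; keeping previous centroid")
            continue
        C[k] = mean / norm
    bank.B[bank.n_samples :] = C
    return CentroidSet(C=C, counts=counts)
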