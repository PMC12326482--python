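"""Synthetic multi-subject feature data and synthetic raw EEG.

The feature generator emulates the statistical structure the method
assumes: per-class Gaussian clusters shared across subjects, a
subject-specific affine domain shift (a small random rotation plus a
translation), an optional session-specific shift of the same form,
far-field outlier contamination, and source-label noise at a controlled
rate eta. Everything is a pure function of (recipe, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .eeg_features import DEFAULT_BANDS

__all__ = [
    "SyntheticRecipe",
    "SyntheticDataset",
    "generate",
    "corrupt_labels",
    "synth_eeg",
    "default_domain_pair",
    "DEFAULT_RECIPE",
]


@dataclass(frozen=True)
class SyntheticRecipe:
    """Study conditions of a synthetic multi-subject dataset.

    ``class_sep`` is the pairwise distance between class means in units of
    the within-class noise standard deviation (simplex layout); the
    constellation sits off-origin at ``constellation_offset`` noise-sd
    units within its own simplex plane, emulating the large common offset
    of log band-power features. ``subject_rotation_deg`` /
    ``subject_translation`` give the magnitude of each subject's affine
    shift -- a rotation about the feature-space origin acting in the
    discriminative plane plus an in-plane translation (noise-sd units) --
    so the stated angle translates into a substantial apparent mean shift
    while leaving within-domain class geometry rigidly intact; the session
    analogues give a weaker within-subject shift. ``outlier_fraction`` of
    samples are replaced by far-field draws at ``outlier_scale`` times the
    noise sd. ``label_noise_eta`` is the percentage of source labels
    replaced by wrong labels.
    """

    n_subjects: int = 2
    n_sessions: int = 1
    n_classes: int = 3
    d: int = 20
    n_per_class: int = 150
    class_sep: float = 6.0
    constellation_offset: float = 20.0
    noise_scale: float = 1.0
    subject_rotation_deg: float = 15.0
    subject_translation: float = 1.0
    session_rotation_deg: float = 5.0
    session_translation: float = 0.3
    outlier_fraction: float = 0.05
    outlier_scale: float = 8.0
    label_noise_eta: float = 0.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.d < self.n_classes - 1:
            raise ValueError("need K >= 2 classes and d >= K - 1 dimensions")
        if not 0 <= self.label_noise_eta <= 100:
            raise ValueError("label_noise_eta is a percentage in [0, 100]")
        if self.class_sep < 2 * self.noise_scale:
            import warnings

            warnings.warn("class separation below twice the noise scale; clusters overlap heavily")


DEFAULT_RECIPE = SyntheticRecipe()


@dataclass
class SyntheticDataset:
    """Per-(subject, session) feature matrices with ground truth and manifest."""

    X: dict  # (subject, session) -> n x d array
    y: dict  # (subject, session) -> n labels
    recipe: SyntheticRecipe
    manifest: dict
    outliers: dict | None = None  # (subject, session) -> boolean mask

    @property
    def subjects(self) -> list:
        return sorted({s for s, _ in self.X})

    @property
    def sessions(self) -> list:
        return sorted({e for _, e in self.X})

    def pooled(self, keys):
        """Concatenate the given (subject, session) blocks."""
        keys = list(keys)
        X = np.vstack([self.X[k] for k in keys])
        y = np.concatenate([self.y[k] for k in keys])
        return X, y


def _simplex_means(K: int, d: int, sep: float, rng: np.random.Generator) -> np.ndarray:
    """K mutually equidistant class means (pairwise distance ``sep``) in a
    random orientation of R^d."""
    # regular simplex in K dims, projected to its (K-1)-dim affine hull
    V = np.eye(K) - np.full((K, K), 1.0 / K)
    # pairwise distance of rows of V is sqrt(2); rescale and embed
    M = np.zeros((K, d))
    M[:, :K] = V * (sep / np.sqrt(2.0))
    Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    return M @ Q.T


def _plane_basis(means: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal basis (2 x d) of the discriminative plane, aligned with
    the simplex: e1 along the first class-difference vector."""
    d = means.shape[1]
    e1 = means[1] - means[0]
    e1 = e1 / np.linalg.norm(e1)
    if means.shape[0] >= 3:
        v = means[2] - means.mean(axis=0)
    else:
        v = rng.standard_normal(d)
    e2 = v - (v @ e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    return np.vstack([e1, e2])


def _in_plane_rotation(U: np.ndarray, angle_deg: float) -> np.ndarray:
    """d x d rotation about the origin acting by ``angle_deg`` inside the
    plane spanned by the rows of ``U`` and as identity elsewhere."""
    d = U.shape[1]
    th = np.deg2rad(angle_deg)
    Rp = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return np.eye(d) + U.T @ (Rp - np.eye(2)) @ U


def generate(recipe: SyntheticRecipe) -> SyntheticDataset:
    """Draw the dataset described by ``recipe`` (deterministic in the seed).

    Subject 0 carries no subject shift (it anchors the common space);
    every other subject gets its own rotation (random sign, stated
    magnitude) plus an in-plane translation. Label noise is NOT applied
    here -- it is a source-domain corruption applied by
    :func:`corrupt_labels` at experiment time.
    """
    rng = np.random.default_rng(recipe.seed)
    K, d, n = recipe.n_classes, recipe.d, recipe.n_per_class
    means0 = _simplex_means(K, d, recipe.class_sep * recipe.noise_scale, rng)
    U = _plane_basis(means0, rng)
    means = means0 + recipe.constellation_offset * recipe.noise_scale * U[1]

    def in_plane_translation(norm: float) -> np.ndarray:
        coef = rng.standard_normal(2)
        tdir = coef @ U
        return tdir / np.linalg.norm(tdir) * norm * recipe.noise_scale

    X, Y, O, manifest = {}, {}, {}, {"shifts": {}}
    for subj in range(recipe.n_subjects):
        if subj == 0:
            Rs, ts = np.eye(d), np.zeros(d)
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            Rs = _in_plane_rotation(U, sign * recipe.subject_rotation_deg)
            ts = in_plane_translation(recipe.subject_translation)
        for sess in range(recipe.n_sessions):
            if sess == 0:
                Re, te = np.eye(d), np.zeros(d)
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                Re = _in_plane_rotation(U, sign * recipe.session_rotation_deg)
                te = in_plane_translation(recipe.session_translation)
            R, t = Re @ Rs, Re @ ts + te
            labels = np.repeat(np.arange(K), n)
            samples = means[labels] + rng.normal(0, recipe.noise_scale, size=(K * n, d))
            samples = samples @ R.T + t
            n_out = int(round(recipe.outlier_fraction * len(samples)))
            out_idx = rng.choice(len(samples), size=n_out, replace=False) if n_out else np.array([], int)
            if n_out:
                center = samples.mean(axis=0)
                dirs = rng.standard_normal((n_out, d))
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
                radii = recipe.outlier_scale * recipe.noise_scale * (1 + rng.random(n_out))
                samples[out_idx] = center + dirs * radii[:, None]
            outmask = np.zeros(len(samples), dtype=bool)
            outmask[out_idx] = True
            perm = rng.permutation(len(samples))
            X[(subj, sess)] = samples[perm]
            Y[(subj, sess)] = labels[perm]
            O[(subj, sess)] = outmask[perm]
            manifest["shifts"][f"{subj}:{sess}"] = {
                "rotation_deg": 0.0 if subj == 0 else recipe.subject_rotation_deg,
                "translation": float(np.linalg.norm(t)),
                "n_outliers": n_out,
            }
    manifest["recipe"] = asdict(recipe)
    return SyntheticDataset(X=X, y=Y, recipe=recipe, manifest=manifest, outliers=O)


def corrupt_labels(labels: np.ndarray, eta_percent: float, seed: int) -> np.ndarray:
    """Replace exactly round(eta% * n) labels with random WRONG labels.

    The replacement class is drawn uniformly from the other K-1 classes, so
    eta is an effective error rate (for K = 2, eta = 100 flips every label).
    """
    if not 0 <= eta_percent <= 100:
        raise ValueError("eta_percent must be in [0, 100]")
    labels = np.asarray(labels, dtype=int)
    K = int(labels.max()) + 1
    n_corrupt = int(round(eta_percent / 100.0 * len(labels)))
    out = labels.copy()
    if n_corrupt == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(labels), size=n_corrupt, replace=False)
    offsets = rng.integers(1, K, size=n_corrupt)
    out[idx] = (labels[idx] + offsets) % K
    return out


def synth_eeg(
    channels: int,
    fs: float,
    duration_s: float,
    band_powers: dict,
    seed: int = 0,
    broadband_floor: float = 1e-6,
) -> np.ndarray:
    """Synthetic raw EEG: per-band Gaussian noise with exact empirical power.

    Each band component is white noise restricted to the band by a DFT
    mask and rescaled so its empirical variance equals the requested
    ``band_powers`` value exactly; a small broadband floor is added. Band
    keys must be among the five standard bands.
    """
    unknown = set(band_powers) - set(DEFAULT_BANDS)
    if unknown:
        raise ValueError(f"unknown bands: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    out = rng.normal(0, np.sqrt(broadband_floor), size=(channels, n))
    for name, power in band_powers.items():
        if power <= 0:
            continue
        lo, hi = DEFAULT_BANDS[name]
        mask = (freqs >= lo) & (freqs <= hi)
        comp = np.fft.irfft(np.fft.rfft(rng.standard_normal((channels, n)), axis=-1) * mask, n=n, axis=-1)
        comp /= comp.std(axis=-1, keepdims=True)
        out += comp * np.sqrt(power)
    return out


def default_domain_pair(seed: int = 7, eta_percent: float = 0.0):
    """The default two-domain adaptation problem: subject 0 of the default
    recipe as labeled source, subject 1 (rotated + translated) as target.

    Returns ``(source, target)`` as :class:`~dadpc.trainer.DomainDataset`;
    target labels are attached for evaluation only. ``eta_percent`` applies
    label noise to the source labels.
    """
    from .trainer import DomainDataset

    recipe = SyntheticRecipe(seed=seed)
    ds = generate(recipe)
    Xs, ys = ds.X[(0, 0)], ds.y[(0, 0)]
    Xt, yt = ds.X[(1, 0)], ds.y[(1, 0)]
    if eta_percent:
        ys = corrupt_labels(ys, eta_percent, seed=seed + 1)
    return DomainDataset(X=Xs, y=ys), DomainDataset(X=Xt, y=yt)
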