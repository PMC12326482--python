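"""Differential-entropy (DE) features from segmented multichannel EEG.

DE of a band-filtered window is computed under the Gaussian convention,
DE = 1/2 * ln(2*pi*e*var), natural log, the standard feature of the
EEG-emotion literature. The five default bands are Delta 1-3 Hz, Theta
4-7 Hz, Alpha 8-13 Hz, Beta 14-30 Hz and Gamma 31-50 Hz; a 62-channel
montage therefore yields 310 features per 1-second segment, a 32-channel
montage 160.

Band selection inside :func:`de_features` uses an ideal zero-phase
DFT-mask filter per window (exactly unit passband gain, infinite stopband
attenuation, inclusive band edges), so the window's mean-square value is
exactly its in-band power. The broadband pre-filter :func:`bandpass` is a
conventional zero-phase forward-backward Butterworth IIR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "DEFAULT_BANDS",
    "EegSegmentSet",
    "segment",
    "bandpass",
    "de_features",
    "resample",
]

DEFAULT_BANDS = {
    "Delta": (1.0, 3.0),
    "Theta": (4.0, 7.0),
    "Alpha": (8.0, 13.0),
    "Beta": (14.0, 30.0),
    "Gamma": (31.0, 50.0),
}

_VAR_FLOOR = 1e-12


@dataclass
class EegSegmentSet:
    """Segmented recording: ``data`` is segments x channels x time."""

    data: np.ndarray
    fs: float
    channel_names: list = field(default_factory=list)
    band_defs: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be segments x channels x time")
        highest = max(hi for _, hi in self.band_defs.values())
        if not self.fs > 2 * highest:
            raise ValueError(
                f"sampling rate {self.fs} Hz cannot resolve the {highest} Hz band edge"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]


def segment(raw: np.ndarray, fs: float, window_s: float = 1.0) -> EegSegmentSet:
    """Cut a channels x time recording into non-overlapping windows.

    The trailing remainder shorter than one window is dropped. A 185-s
    trial at 200 Hz yields 185 one-second segments.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    win = int(round(window_s * fs))
    n = raw.shape[1] // win
    if n < 1:
        raise ValueError("recording shorter than one window")
    segs = raw[:, : n * win].reshape(raw.shape[0], n, win).transpose(1, 0, 2)
    return EegSegmentSet(data=segs, fs=fs)


def bandpass(raw: np.ndarray, fs: float, low: float = 0.3, high: float = 50.0, order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth band-pass over the time (last) axis.

    Realised as a second-order high-pass at ``low`` cascaded with an
    ``order``-pole low-pass at ``high``, each applied forward-backward on a
    zero-padded extension (pad length 4/low seconds) so the very low
    high-pass corner settles outside the data instead of leaking edge
    transients into it.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(f"invalid band edges ({low}, {high}) at fs={fs}")
    x = np.asarray(raw, dtype=float)
    hp = signal.butter(2, low, btype="highpass", fs=fs, output="sos")
    lp = signal.butter(order, high, btype="lowpass", fs=fs, output="sos")
    pad = int(round(4 * fs / low))
    shape = list(x.shape)
    shape[-1] = pad
    zeros = np.zeros(shape)
    ext = np.concatenate([zeros, x, zeros], axis=-1)
    y = signal.sosfiltfilt(hp, ext, axis=-1, padlen=0)
    y = signal.sosfiltfilt(lp, y, axis=-1, padlen=0)
    return y[..., pad : pad + x.shape[-1]]


def _band_power(window: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    """Mean-square in-band power of each row via an ideal DFT-mask filter."""
    n = window.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(window, axis=-1)
    spec = spec * mask
    filtered = np.fft.irfft(spec, n=n, axis=-1)
    return np.mean(filtered**2, axis=-1)


def de_features(segments: EegSegmentSet) -> pd.DataFrame:
    """Per-segment differential entropy for every (channel, band) pair.

    Columns are ordered channel-major and named ``<channel>_<band>``.
    Zero-power windows are floored at var = 1e-12 so DE stays finite.
    """
    nyq = segments.fs / 2
    for name, (lo, hi) in segments.band_defs.items():
        if not (0 < lo < hi < nyq):
            raise ValueError(f"band {name} ({lo}-{hi} Hz) outside (0, Nyquist)")
    n_seg, n_ch, _ = segments.data.shape
    bands = list(segments.band_defs.items())
    out = np.empty((n_seg, n_ch * len(bands)))
    for bi, (name, (lo, hi)) in enumerate(bands):
        power = _band_power(segments.data, segments.fs, lo, hi)  # n_seg x n_ch
        de = 0.5 * np.log(2 * np.pi * np.e * np.maximum(power, _VAR_FLOOR))
        for ci in range(n_ch):
            out[:, ci * len(bands) + bi] = de[:, ci]
    cols = [f"{ch}_{name}" for ch in segments.channel_names for name, _ in bands]
    return pd.DataFrame(out, columns=cols)


def resample(raw: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling helper (e.g. 512 -> 128 Hz) over the last axis."""
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return signal.resample_poly(np.asarray(raw, dtype=float), frac.numerator, frac.denominator, axis=-1)
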