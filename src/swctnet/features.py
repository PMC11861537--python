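"""Time- and frequency-domain sEMG window features.

Six classical features per EMG window: root-mean-square (RMS), mean
absolute value (MAV), zero-crossing count (ZC), waveform length (WL),
slope-sign-change count (SSC) and mean power frequency (MPF, the spectral
centroid of a Welch power-spectral-density estimate).  RMS/MAV track
contraction intensity, ZC/MPF track frequency content (MPF drifts down
with fatigue), WL and SSC track waveform complexity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "FeatureVector",
    "SpectrumEstimate",
    "FEATURE_NAMES",
    "extract_features",
    "estimate_psd",
    "feature_targets_for_dataset",
]

FEATURE_NAMES = ("rms", "mav", "zc", "wl", "ssc", "mpf")


@dataclass(frozen=True)
class FeatureVector:
    """Six features for one EMG channel within one window."""

    rms: float
    mav: float
    zc: float
    wl: float
    ssc: float
    mpf: float
    window_id: int = -1
    channel: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.rms, self.mav, self.zc, self.wl, self.ssc, self.mpf])


@dataclass
class SpectrumEstimate:
    """One-sided power spectral density on [0, fs/2]."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power spectral density must be nonnegative")


def estimate_psd(window: np.ndarray, fs: float) -> SpectrumEstimate:
    """Welch power-spectral-density estimate of one window.

    Hann-tapered segments of length ``N // 4`` (at least 8) with 50 %
    overlap, density scaling, no detrending — so the integral of the
    density approximates the signal's mean square power.
    """
    window = np.asarray(window, dtype=float)
    n = window.size
    if n < 8:
        raise ValueError(f"PSD estimation needs at least 8 samples, got {n}")
    nperseg = max(8, n // 4)
    freqs, power = _signal.welch(
        window, fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend=False, scaling="density",
    )
    return SpectrumEstimate(freqs=freqs, power=power)


def _mean_power_frequency(spec: SpectrumEstimate) -> float:
    total = spec.power.sum()
    if total <= 0.0:
        return 0.0
    return float((spec.freqs * spec.power).sum() / total)


def extract_features(window: np.ndarray, fs: float,
                     epsilon: float | None = None,
                     zc_mode: str = "sign_change",
                     window_id: int = -1, channel: str = "") -> FeatureVector:
    """Compute the six features of one EMG window.

    Parameters
    ----------
    window:
        1-D signal of length N >= 3.
    fs:
        Sampling rate in Hz.
    epsilon:
        Zero-crossing threshold.  Defaults to ``1e-4`` of the window's
        peak absolute amplitude.
    zc_mode:
        ``"sign_change"`` (default) counts adjacent pairs with
        ``x[n] * x[n+1] < 0`` and ``|x[n] - x[n+1]| >= epsilon`` — the
        standard zero-crossing definition.  ``"literal"`` counts pairs
        with ``|x[n] * x[n+1]| < epsilon`` (a near-zero-product rule
        sometimes printed in the literature).
    """
    x = np.asarray(window, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError(f"window must have at least 3 samples, got {n}")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if epsilon is None:
        peak = np.abs(x).max()
        epsilon = 1e-4 * peak
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")

    rms = float(np.sqrt(np.mean(x ** 2)))
    mav = float(np.mean(np.abs(x)))

    prod = x[:-1] * x[1:]
    if zc_mode == "sign_change":
        zc = float(np.count_nonzero((prod < 0) & (np.abs(np.diff(x)) >= epsilon)))
    elif zc_mode == "literal":
        zc = float(np.count_nonzero(np.abs(prod) < epsilon))
    else:
        raise ValueError(f"unknown zc_mode {zc_mode!r}")

    wl = float(np.sum(np.abs(np.diff(x))))
    # slope sign changes at interior points: (x[n]-x[n-1]) * (x[n+1]-x[n]) < 0
    d = np.diff(x)
    ssc = float(np.count_nonzero(d[:-1] * d[1:] < 0))

    mpf = _mean_power_frequency(estimate_psd(x, fs)) if n >= 8 else 0.0
    return FeatureVector(rms, mav, zc, wl, ssc, mpf,
                         window_id=window_id, channel=channel)


def feature_targets_for_dataset(windows, fs: float,
                                epsilon: float | None = None,
                                channel_names: list[str] | None = None,
                                zc_mode: str = "sign_change") -> pd.DataFrame:
    """Feature table for a collection of multichannel EMG windows.

    Parameters
    ----------
    windows:
        Iterable of ``(n_channels, n)`` arrays (or objects with an
        ``emg_window`` attribute), one per window, indexed by position.

    Returns
    -------
    pandas.DataFrame
        One row per (window, channel): columns ``window_id, channel,
        rms, mav, zc, wl, ssc, mpf``.
    """
    rows = []
    for wid, w in enumerate(windows):
        arr = np.asarray(getattr(w, "emg_window", w), dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        for c in range(arr.shape[0]):
            name = channel_names[c] if channel_names else f"ch{c}"
            try:
                fv = extract_features(arr[c], fs, epsilon=epsilon,
                                      zc_mode=zc_mode, window_id=wid, channel=name)
            except ValueError as exc:
                raise ValueError(f"window {wid}, channel {name}: {exc}") from exc
            rows.append({"window_id": wid, "channel": name,
                         **{k: getattr(fv, k) for k in FEATURE_NAMES}})
    return pd.DataFrame(rows, columns=["window_id", "channel", *FEATURE_NAMES])
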