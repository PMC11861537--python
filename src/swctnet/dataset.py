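"""Dataset construction: sliding windows, leakage-free splits, normalization.

Aligned IMU/EMG streams are segmented into fixed-length sliding windows
(default 200 ms, i.e. 40 points at 200 Hz, step 50 ms); each window keeps
the native-rate EMG covering the same time span so features can be
computed before downsampling.  Samples are split 70/20/10 per movement at
repetition granularity — every window of one repetition lands in the same
subset, so overlapping windows can never straddle subsets — with
healthy/injured proportions preserved per stratum.  Channel-wise z-score
normalization statistics are estimated on the training subset only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WindowedSample",
    "NormalizationStats",
    "DatasetSplit",
    "window_count",
    "segment_windows",
    "split_dataset",
    "fit_normalizer",
    "apply_normalizer",
]


@dataclass
class WindowedSample:
    """One training unit: synchronized IMU and EMG windows plus metadata."""

    imu_window: np.ndarray          # (n_imu_channels, L_pts)
    emg_window: np.ndarray          # (n_emg_channels, L_pts * fs_ratio)
    movement_label: int
    participant_id: int
    round_id: int
    repetition: int
    group: str                      # "healthy" | "injured"
    window_id: int = -1
    start_time: float = 0.0
    features: np.ndarray | None = None      # (n_emg_channels, 6) targets
    envelope_rms: np.ndarray | None = None  # ground-truth envelope RMS/channel

    @property
    def repetition_key(self) -> tuple:
        return (self.participant_id, self.movement_label,
                self.round_id, self.repetition)


@dataclass
class NormalizationStats:
    """Per-channel z-score statistics estimated on training data only."""

    imu_mu: np.ndarray
    imu_sigma: np.ndarray
    emg_mu: np.ndarray
    emg_sigma: np.ndarray

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist()
                for k in ("imu_mu", "imu_sigma", "emg_mu", "emg_sigma")}


@dataclass
class DatasetSplit:
    """Disjoint train/val/test collections with shared normalization."""

    train: list[WindowedSample]
    val: list[WindowedSample]
    test: list[WindowedSample]
    normalization: NormalizationStats | None = None
    manifest: dict = field(default_factory=dict)

    def subsets(self):
        return {"train": self.train, "val": self.val, "test": self.test}


def window_count(n_samples: int, L_pts: int, S_pts: int) -> int:
    """Number of complete sliding windows: floor((n - L)/S) + 1, or 0."""
    if n_samples < L_pts:
        return 0
    return (n_samples - L_pts) // S_pts + 1


def segment_windows(imu: np.ndarray, emg: np.ndarray,
                    imu_fs: float = 200.0, emg_fs: float = 2000.0,
                    L_ms: float = 200.0, S_ms: float = 50.0,
                    t0: float = 0.0, **meta) -> list[WindowedSample]:
    """Segment one aligned repetition into sliding windows.

    Window k covers IMU samples ``[k*S_pts, k*S_pts + L_pts)``; the EMG
    window covers the same time span at the native EMG rate (the rate
    ratio must be an integer).  Incomplete trailing windows are dropped.
    Returns an empty list (rather than raising) when the stream is
    shorter than one window.
    """
    if L_ms <= 0 or S_ms <= 0:
        raise ValueError("window length and step must be positive")
    imu = np.atleast_2d(np.asarray(imu, dtype=float))
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    ratio = emg_fs / imu_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("emg_fs must be an integer multiple of imu_fs")
    ratio = int(round(ratio))
    L_pts = int(round(L_ms * imu_fs / 1000.0))
    S_pts = int(round(S_ms * imu_fs / 1000.0))
    n = min(imu.shape[1], emg.shape[1] // ratio)
    k = window_count(n, L_pts, S_pts)
    out = []
    for i in range(k):
        a = i * S_pts
        out.append(WindowedSample(
            imu_window=imu[:, a:a + L_pts].copy(),
            emg_window=emg[:, a * ratio:(a + L_pts) * ratio].copy(),
            window_id=i,
            start_time=t0 + a / imu_fs,
            movement_label=meta.get("movement_label", -1),
            participant_id=meta.get("participant_id", -1),
            round_id=meta.get("round_id", 0),
            repetition=meta.get("repetition", 0),
            group=meta.get("group", "healthy"),
        ))
    return out


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Integer allocation of n items by the largest-remainder rule."""
    exact = [n * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)])  # most-negative first
    for idx in order[:short]:
        base[idx] += 1
    return base


def split_dataset(samples: list[WindowedSample],
                  ratios: tuple[float, float, float] = (0.70, 0.20, 0.10),
                  seed: int = 0) -> DatasetSplit:
    """Repetition-atomic 70/20/10 split stratified by movement and group.

    All windows of one repetition go to the same subset, which guarantees
    both stated constraints at once: each repetition is an independent
    sample, and overlapping consecutive windows can never leak across
    subsets.  Within each (movement, group) stratum, repetitions are
    shuffled under ``seed`` and allocated to train/val/test by the
    largest-remainder rule.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    by_rep: dict[tuple, list[WindowedSample]] = {}
    for s in samples:
        by_rep.setdefault(s.repetition_key, []).append(s)

    # repetitions per (movement, group) stratum
    strata: dict[tuple, list[tuple]] = {}
    reps_per_movement: dict[int, int] = {}
    for key in by_rep:
        movement = key[1]
        group = by_rep[key][0].group
        strata.setdefault((movement, group), []).append(key)
        reps_per_movement[movement] = reps_per_movement.get(movement, 0) + 1
    for movement, n_reps in reps_per_movement.items():
        if n_reps < 10:
            raise ValueError(
                f"movement {movement} has only {n_reps} repetitions; "
                "at least 10 are needed to realize a 10% test share"
            )

    rng = np.random.default_rng(seed)
    subsets: dict[str, list[WindowedSample]] = {"train": [], "val": [], "test": []}
    assignment: dict[str, list] = {"train": [], "val": [], "test": []}
    for stratum in sorted(strata):
        keys = sorted(strata[stratum])
        rng.shuffle(keys)
        n_tr, n_va, n_te = _largest_remainder(len(keys), ratios)
        chunks = (keys[:n_tr], keys[n_tr:n_tr + n_va], keys[n_tr + n_va:])
        for name, chunk in zip(("train", "val", "test"), chunks):
            for key in chunk:
                subsets[name].extend(by_rep[key])
                assignment[name].append(list(key))
    manifest = {
        "seed": int(seed),
        "ratios": list(ratios),
        "n_samples": {k: len(v) for k, v in subsets.items()},
        "repetitions": assignment,
    }
    return DatasetSplit(subsets["train"], subsets["val"], subsets["test"],
                        manifest=manifest)


def fit_normalizer(train: list[WindowedSample],
                   sigma_floor: float = 1e-8) -> NormalizationStats:
    """Per-channel mean and standard deviation from the training subset only."""
    if not train:
        raise ValueError("training subset is empty")
    imu = np.concatenate([s.imu_window for s in train], axis=1)
    emg = np.concatenate([s.emg_window for s in train], axis=1)
    stats = NormalizationStats(
        imu_mu=imu.mean(axis=1), imu_sigma=imu.std(axis=1),
        emg_mu=emg.mean(axis=1), emg_sigma=emg.std(axis=1),
    )
    stats.imu_sigma = np.maximum(stats.imu_sigma, sigma_floor)
    stats.emg_sigma = np.maximum(stats.emg_sigma, sigma_floor)
    return stats


def apply_normalizer(stats: NormalizationStats,
                     samples: list[WindowedSample]) -> list[WindowedSample]:
    """Return z-scored copies of ``samples`` using training-set statistics."""
    out = []
    for s in samples:
        ns = WindowedSample(
            imu_window=(s.imu_window - stats.imu_mu[:, None]) / stats.imu_sigma[:, None],
            emg_window=(s.emg_window - stats.emg_mu[:, None]) / stats.emg_sigma[:, None],
            movement_label=s.movement_label, participant_id=s.participant_id,
            round_id=s.round_id, repetition=s.repetition, group=s.group,
            window_id=s.window_id, start_time=s.start_time,
            features=s.features, envelope_rms=s.envelope_rms,
        )
        out.append(ns)
    return out
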