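"""Preprocessing of raw IMU / sEMG streams.

Turns raw multichannel sensor recordings into clean, band-limited,
temporally aligned signals at a common rate: coordinate transformation of
IMU triads into the global frame, Euler-angle estimation from accelerometer
and magnetometer data, zero-phase Butterworth band-pass filtering of sEMG,
block-mean downsampling, and timestamp-based stream alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "GRAVITY",
    "RawRecording",
    "OrientationSeries",
    "FilterSpec",
    "AlignmentReport",
    "to_global_frame",
    "compute_euler_angles",
    "butterworth_bandpass",
    "downsample_mean",
    "align_streams",
]

#: Standard gravitational acceleration (m/s^2).
GRAVITY = 9.80665


@dataclass
class RawRecording:
    """One multichannel sensor stream.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)``.
    fs:
        Sampling rate in Hz (> 0).
    timestamps:
        Strictly increasing per-sample times in seconds, length
        ``n_samples``.
    channel_names:
        One label per channel.
    modality:
        Either ``"imu"`` or ``"emg"``.  IMU recordings must have a channel
        count that is a multiple of 3 (axis triads).
    """

    data: np.ndarray
    fs: float
    timestamps: np.ndarray
    channel_names: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.timestamps.shape != (self.data.shape[1],):
            raise ValueError("timestamps length must equal n_samples")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name per channel required")
        if self.modality not in ("imu", "emg"):
            raise ValueError("modality must be 'imu' or 'emg'")
        if self.modality == "imu" and self.data.shape[0] % 3 != 0:
            raise ValueError("IMU recordings must have channel triads (multiple of 3)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.data.copy(), self.fs, self.timestamps.copy(),
            list(self.channel_names), self.modality,
        )


@dataclass
class OrientationSeries:
    """Euler angles (radians) of a rigid body over time.

    ``roll_phi`` and ``yaw_psi`` live in (-pi, pi]; ``pitch_theta`` in
    [-pi/2, pi/2].  Samples that could not be evaluated are NaN.
    """

    roll_phi: np.ndarray
    pitch_theta: np.ndarray
    yaw_psi: np.ndarray
    fs: float
    n_flagged: int = 0

    def __post_init__(self) -> None:
        n = len(self.roll_phi)
        if not (len(self.pitch_theta) == len(self.yaw_psi) == n):
            raise ValueError("angle series must have equal length")


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter specification: order and passband edges in Hz."""

    order: int = 4
    low_hz: float = 10.0
    high_hz: float = 500.0
    fs: float = 2000.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be a positive integer")
        if not (0.0 < self.low_hz < self.high_hz < self.fs / 2.0):
            raise ValueError(
                "passband edges must satisfy 0 < low < high < fs/2 "
                f"(got {self.low_hz}-{self.high_hz} Hz at fs={self.fs})"
            )


@dataclass
class AlignmentReport:
    """Outcome of timestamp-based stream alignment."""

    pairs: np.ndarray            # (n_pairs, 2) indices into (emg, imu)
    n_discarded_emg: int
    n_discarded_imu: int
    max_offset: float            # largest |t_emg - t_imu| among kept pairs

    def to_dict(self) -> dict:
        return {
            "pairs_kept": int(self.pairs.shape[0]),
            "discarded_emg": int(self.n_discarded_emg),
            "discarded_imu": int(self.n_discarded_imu),
            "max_offset_s": float(self.max_offset),
        }


def to_global_frame(local: RawRecording, rotations: np.ndarray,
                    tol: float = 1e-6) -> RawRecording:
    """Rotate each sensor-frame sample triad into the global frame.

    Applies ``g_global[i] = R_i @ g_local[i]`` per sample, for each axis
    triad of the recording.

    Parameters
    ----------
    local:
        IMU recording whose channels form (x, y, z) triads.
    rotations:
        Array of shape ``(n_samples, 3, 3)``; each matrix must be a proper
        rotation (orthonormal, det +1) within ``tol``.
    """
    rotations = np.asarray(rotations, dtype=float)
    if rotations.shape != (local.n_samples, 3, 3):
        raise ValueError(
            f"expected one 3x3 rotation per sample, got shape {rotations.shape}"
        )
    eye = np.eye(3)
    err = np.abs(rotations.transpose(0, 2, 1) @ rotations - eye).max(axis=(1, 2))
    if np.any(err > tol):
        raise ValueError(
            f"non-orthonormal rotation matrices (max |R^T R - I| = {err.max():.2e})"
        )
    if np.any(np.linalg.det(rotations) < 0):
        raise ValueError("rotation matrices must have determinant +1")

    out = local.data.copy()
    for c0 in range(0, local.n_channels, 3):
        triad = local.data[c0:c0 + 3, :].T            # (n, 3)
        out[c0:c0 + 3, :] = np.einsum("nij,nj->ni", rotations, triad).T
    rec = local.copy()
    rec.data = out
    return rec


def compute_euler_angles(accel: np.ndarray, mag: np.ndarray,
                         g: float = GRAVITY, fs: float = 200.0,
                         clip_tol: float = 1e-6) -> OrientationSeries:
    """Estimate roll/pitch/yaw from accelerometer and magnetometer data.

    Roll ``phi = atan2(a_y, a_z)``, pitch ``theta = arcsin(-a_x / g)``,
    yaw ``psi = atan2(m_y, m_x)``.  Four-quadrant ``atan2`` is used in
    place of a plain arctangent so quadrant information is kept.  The
    arcsin argument is clipped to [-1, 1] within ``clip_tol``; samples
    whose argument exceeds the tolerance are flagged NaN and counted in
    :attr:`OrientationSeries.n_flagged`.

    The yaw estimate uses only the horizontal magnetometer components and
    performs no tilt compensation, so it is only exact when the sensor is
    level.
    """
    accel = np.asarray(accel, dtype=float)
    mag = np.asarray(mag, dtype=float)
    if accel.shape[0] != 3 or mag.shape[0] < 2:
        raise ValueError("accel must be 3xN; mag must provide x and y rows")
    if accel.shape[1] != mag.shape[1]:
        raise ValueError("accelerometer and magnetometer lengths differ")

    phi = np.arctan2(accel[1], accel[2])
    arg = -accel[0] / g
    bad = np.abs(arg) > 1.0 + clip_tol
    theta = np.arcsin(np.clip(arg, -1.0, 1.0))
    theta[bad] = np.nan
    psi = np.arctan2(mag[1], mag[0])
    return OrientationSeries(phi, theta, psi, fs=fs, n_flagged=int(bad.sum()))


def butterworth_bandpass(x: RawRecording, spec: FilterSpec) -> RawRecording:
    """Zero-phase Butterworth band-pass filtering of every channel.

    The digital filter is designed from the analog Butterworth prototype
    (bilinear transform, pre-warped edges) and applied forward-backward
    (``sosfiltfilt``), so no group delay is introduced and temporal
    alignment with other streams is preserved.  Forward-backward
    application doubles the effective order.
    """
    if spec.fs != x.fs:
        raise ValueError(f"filter designed for fs={spec.fs} but recording has fs={x.fs}")
    min_len = 3 * (2 * spec.order + 1)
    if x.n_samples < min_len:
        raise ValueError(
            f"signal too short to filter: {x.n_samples} samples, "
            f"minimum is {min_len} for an order-{spec.order} band-pass"
        )
    sos = _signal.butter(spec.order, [spec.low_hz, spec.high_hz],
                         btype="bandpass", fs=spec.fs, output="sos")
    rec = x.copy()
    rec.data = _signal.sosfiltfilt(sos, x.data, axis=1)
    return rec


def butterworth_magnitude_sq(omega: np.ndarray | float, omega_c: float,
                             order: int) -> np.ndarray | float:
    """Squared magnitude of the analog Butterworth prototype.

    ``|H(j w)|^2 = 1 / (1 + (w / w_c)^(2 n))`` — equals 1/2 at the cutoff
    for any order.
    """
    return 1.0 / (1.0 + (np.asarray(omega, dtype=float) / omega_c) ** (2 * order))


def downsample_mean(x: np.ndarray, M: int) -> np.ndarray:
    """Block-mean downsampling by an integer factor ``M``.

    Output sample ``k`` is the mean of the k-th non-overlapping block of
    ``M`` input samples; a trailing partial block is dropped.  Works on
    1-D signals or (channels, samples) arrays along the last axis.
    """
    if M < 1:
        raise ValueError("downsampling factor M must be a positive integer")
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < M:
        raise ValueError(f"signal length {n} shorter than block size {M}")
    k = n // M
    trimmed = x[..., : k * M]
    return trimmed.reshape(*x.shape[:-1], k, M).mean(axis=-1)


def align_streams(emg: RawRecording, imu: RawRecording,
                  delta_t: float = 0.005) -> AlignmentReport:
    """Pair EMG and IMU samples whose timestamps differ by less than ``delta_t``.

    Both recordings are expected at a common rate (EMG already
    downsampled).  Matching is greedy in time order: each candidate pair
    (i, j) with ``|t_emg[i] - t_imu[j]| < delta_t`` is accepted and each
    sample used at most once; unmatched samples are discarded and counted.

    Raises
    ------
    ValueError
        If no pair satisfies the tolerance; the message reports the
        smallest offset observed.
    """
    te, ti = emg.timestamps, imu.timestamps
    pairs: list[tuple[int, int]] = []
    i = j = 0
    max_off = 0.0
    min_seen = np.inf
    while i < len(te) and j < len(ti):
        off = te[i] - ti[j]
        min_seen = min(min_seen, abs(off))
        if abs(off) < delta_t:
            pairs.append((i, j))
            max_off = max(max_off, abs(off))
            i += 1
            j += 1
        elif off < 0:
            i += 1
        else:
            j += 1
    if not pairs:
        raise ValueError(
            f"no samples aligned within {delta_t * 1e3:.3g} ms; "
            f"smallest observed offset was {min_seen * 1e3:.3g} ms"
        )
    arr = np.asarray(pairs, dtype=int)
    return AlignmentReport(
        pairs=arr,
        n_discarded_emg=len(te) - arr.shape[0],
        n_discarded_imu=len(ti) - arr.shape[0],
        max_offset=max_off,
    )
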