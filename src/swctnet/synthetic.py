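"""Seeded generator of paired IMU/sEMG shoulder-movement sessions.

Emulates the statistical structure the cross-modal method assumes: each
subject performs three shoulder movements (abduction, forward flexion,
internal/external rotation), ten repetitions of 5 s separated by 2 s of
rest.  Joint-angle trajectories are smooth and periodic with a
movement-specific axis and oscillation frequency; the accelerometer
reads gravity rotated into the moving frame (plus an optional motion
term and white noise), the gyroscope reads Euler-angle rates, and the
magnetometer reads a fixed horizontal field rotated by yaw (no tilt —
matching the tilt-free yaw estimate used downstream).

Muscle activity is coupled to kinematics: each muscle's activation
envelope is a rectified linear mix of the absolute angular-velocity
components with a muscle-specific gain and an electromechanical-delay
latency; the EMG is that envelope modulating band-limited 20-150 Hz
noise on a 0-1.5 mV scale, plus baseline drift and power-line
interference.  A pathological variant injects amplitude dropouts,
tremor bursts, envelope jitter and extra non-stationary noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .dataset import (DatasetSplit, WindowedSample, apply_normalizer,
                      fit_normalizer, segment_windows, split_dataset)
from .features import FEATURE_NAMES, extract_features
from .preprocess import (GRAVITY, FilterSpec, OrientationSeries, RawRecording,
                         align_streams, butterworth_bandpass, downsample_mean)

__all__ = [
    "ScenarioConfig", "SyntheticSession", "MOVEMENTS", "EMG_CHANNELS",
    "generate_kinematics", "emg_from_kinematics", "generate_session",
    "pathological_variant", "make_benchmark", "generation_sequences",
]

MOVEMENTS = ("abduction", "flexion", "rotation")
EMG_CHANNELS = ("Del", "Trap", "Bicep", "Tricep", "Lat")
IMU_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z",
                "mag_x", "mag_y", "mag_z")

# Per-muscle coupling gains (mV per rad/s) onto |d(roll)/dt|, |d(pitch)/dt|,
# |d(yaw)/dt|.  Fixed, documented constants: each muscle weights the three
# rotation axes differently so the five envelopes are distinguishable.
COUPLING_GAINS = {
    "Del":    (0.40, 0.20, 0.05),
    "Trap":   (0.25, 0.30, 0.10),
    "Bicep":  (0.10, 0.35, 0.15),
    "Tricep": (0.15, 0.10, 0.30),
    "Lat":    (0.05, 0.15, 0.35),
}

# movement signatures: (primary axis index, amplitude rad, wobble Hz)
_MOVEMENT_SIGNATURES = {
    "abduction": (0, 1.2, 0.8),
    "flexion":   (1, 1.0, 1.2),
    "rotation":  (2, 1.0, 1.6),
}


@dataclass
class ScenarioConfig:
    """Study-protocol and noise parameters of the synthetic scenario."""

    n_subjects: int = 2
    healthy_fraction: float = 0.5
    movements: tuple = MOVEMENTS
    repetitions: int = 10
    rounds: int = 1
    rep_duration: float = 5.0        # seconds of movement per repetition
    rest_duration: float = 2.0       # seconds of rest between repetitions
    imu_fs: float = 200.0
    emg_fs: float = 2000.0
    emg_channels: tuple = EMG_CHANNELS
    # IMU noise (standard deviations) and motion-acceleration gain
    accel_noise: float = 0.05        # m/s^2
    gyro_noise: float = 0.01         # rad/s
    mag_noise: float = 0.005         # field units
    linear_accel_gain: float = 0.2   # m/s^2 per rad/s^2 (lever-arm proxy)
    # EMG composition (mV scale)
    coupling_scale: float = 1.0      # multiplies COUPLING_GAINS
    emg_noise_floor: float = 0.01    # mV, always-present sensor noise
    drift_amplitude: float = 0.002   # mV baseline drift (1-4 uV scale)
    line_amplitude: float = 0.008    # mV power-line interference
    line_hz: float = 50.0
    latency: float = 0.05            # s, electromechanical delay
    emg_max: float = 1.5             # mV, physical amplitude bound
    pathology_severity: float = 1.0  # applied to injured subjects
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.healthy_fraction <= 1.0:
            raise ValueError("healthy_fraction must lie in [0, 1]")
        for r in (self.imu_fs, self.emg_fs, self.rep_duration):
            if r <= 0:
                raise ValueError("rates and durations must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["movements"] = list(self.movements)
        d["emg_channels"] = list(self.emg_channels)
        return d


@dataclass
class RepetitionLabel:
    movement: str
    movement_label: int
    round_id: int
    repetition: int
    t_start: float
    t_end: float


@dataclass
class SyntheticSession:
    """One subject's full recording with ground truth."""

    imu: RawRecording                # 9 channels at imu_fs
    emg: RawRecording                # 5 channels at emg_fs
    angles: OrientationSeries        # ground-truth Euler angles at imu_fs
    envelope: np.ndarray             # (5, n_emg) ground-truth activation (mV)
    labels: list[RepetitionLabel]
    participant_id: int
    group: str                       # "healthy" | "injured"

    def rotation_matrices(self) -> np.ndarray:
        """Ground-truth per-sample rotation matrices R = Rz(psi)Ry(theta)Rx(phi)."""
        phi, th, psi = (self.angles.roll_phi, self.angles.pitch_theta,
                        self.angles.yaw_psi)
        cph, sph = np.cos(phi), np.sin(phi)
        cth, sth = np.cos(th), np.sin(th)
        cps, sps = np.cos(psi), np.sin(psi)
        n = len(phi)
        R = np.empty((n, 3, 3))
        R[:, 0, 0] = cps * cth
        R[:, 0, 1] = cps * sth * sph - sps * cph
        R[:, 0, 2] = cps * sth * cph + sps * sph
        R[:, 1, 0] = sps * cth
        R[:, 1, 1] = sps * sth * sph + cps * cph
        R[:, 1, 2] = sps * sth * cph - cps * sph
        R[:, 2, 0] = -sth
        R[:, 2, 1] = cth * sph
        R[:, 2, 2] = cth * cph
        return R


def _smooth_profile(t: np.ndarray, duration: float) -> np.ndarray:
    """Raise-and-lower repetition profile: sin^2 ramp over the repetition."""
    return np.sin(np.pi * t / duration) ** 2


def _movement_angles(movement: str, t: np.ndarray, duration: float,
                     rng: np.random.Generator) -> np.ndarray:
    """(3, n) roll/pitch/yaw trajectory for one repetition."""
    axis, amp, wobble_hz = _MOVEMENT_SIGNATURES[movement]
    base = amp * _smooth_profile(t, duration)
    phase = rng.uniform(0, 2 * np.pi)
    wobble = 0.15 * amp * _smooth_profile(t, duration) * np.sin(
        2 * np.pi * wobble_hz * t + phase)
    angles = np.zeros((3, t.size))
    angles[axis] = base + wobble
    # small secondary motion on the other axes keeps trajectories 3-D
    for other in range(3):
        if other != axis:
            angles[other] = 0.1 * base * np.sin(
                2 * np.pi * 0.2 * t + phase + other)
    return angles


def generate_kinematics(cfg: ScenarioConfig, movement: str,
                        rng: np.random.Generator, round_id: int = 0,
                        label_offset: float = 0.0):
    """Angle trajectories and IMU channels for one movement block.

    One block is ``repetitions`` cycles of (5 s movement + 2 s rest).
    Returns ``(angles, imu_data, labels)`` where ``imu_data`` is the
    (9, n) array of accelerometer, gyroscope and magnetometer channels.
    """
    fs = cfg.imu_fs
    n_rep = int(round(cfg.rep_duration * fs))
    n_rest = int(round(cfg.rest_duration * fs))
    t_rep = np.arange(n_rep) / fs
    movement_label = list(cfg.movements).index(movement)

    blocks, labels = [], []
    t_cursor = label_offset
    for rep in range(cfg.repetitions):
        ang = _movement_angles(movement, t_rep, cfg.rep_duration, rng)
        blocks.append(ang)
        blocks.append(np.zeros((3, n_rest)))
        labels.append(RepetitionLabel(
            movement=movement, movement_label=movement_label,
            round_id=round_id, repetition=rep,
            t_start=t_cursor, t_end=t_cursor + cfg.rep_duration))
        t_cursor += cfg.rep_duration + cfg.rest_duration
    angles = np.concatenate(blocks, axis=1)           # (3, n)
    phi, theta, psi = angles
    n = angles.shape[1]

    rates = np.gradient(angles, 1.0 / fs, axis=1)     # rad/s
    accels = np.gradient(rates, 1.0 / fs, axis=1)     # rad/s^2

    g = GRAVITY
    acc = np.empty((3, n))
    acc[0] = -g * np.sin(theta)
    acc[1] = g * np.sin(phi) * np.cos(theta)
    acc[2] = g * np.cos(phi) * np.cos(theta)
    acc += cfg.linear_accel_gain * accels             # motion term
    acc += rng.normal(0.0, cfg.accel_noise, (3, n)) if cfg.accel_noise else 0.0

    gyr = rates + (rng.normal(0.0, cfg.gyro_noise, (3, n))
                   if cfg.gyro_noise else 0.0)

    mag = np.empty((3, n))
    mag[0] = np.cos(psi)
    mag[1] = np.sin(psi)
    mag[2] = 0.5
    mag += rng.normal(0.0, cfg.mag_noise, (3, n)) if cfg.mag_noise else 0.0

    imu_data = np.vstack([acc, gyr, mag])
    series = OrientationSeries(phi.copy(), theta.copy(), psi.copy(), fs=fs)
    return series, imu_data, labels


def _bandlimited_noise(n: int, fs: float, low: float, high: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise band-limited to [low, high] Hz."""
    white = rng.standard_normal(n)
    sos = _signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = _signal.sosfiltfilt(sos, white)
    return x / max(np.sqrt(np.mean(x ** 2)), 1e-12)


def emg_from_kinematics(angles: OrientationSeries, cfg: ScenarioConfig,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """EMG channels coupled to joint kinematics.

    Returns ``(emg, envelope)``, both (n_muscles, n_emg_samples) in mV.
    The activation envelope of each muscle is a gain-weighted mix of the
    absolute Euler-angle rates, delayed by the electromechanical latency
    and low-pass smoothed; the carrier is unit-RMS 20-150 Hz noise.
    """
    fs_imu, fs_emg = angles.fs, cfg.emg_fs
    ratio = int(round(fs_emg / fs_imu))
    ang = np.vstack([angles.roll_phi, angles.pitch_theta, angles.yaw_psi])
    rates = np.abs(np.gradient(ang, 1.0 / fs_imu, axis=1))   # (3, n_imu)
    rates_hi = np.repeat(rates, ratio, axis=1)               # EMG time base
    n = rates_hi.shape[1]
    delay = int(round(cfg.latency * fs_emg))

    sos_env = _signal.butter(2, 5.0, btype="lowpass", fs=fs_emg, output="sos")
    emg = np.empty((len(cfg.emg_channels), n))
    envelope = np.empty_like(emg)
    t = np.arange(n) / fs_emg
    for m, name in enumerate(cfg.emg_channels):
        gains = np.array(COUPLING_GAINS[name]) * cfg.coupling_scale
        env = gains @ rates_hi                               # rectified linear mix
        if delay:
            env = np.concatenate([np.zeros(delay), env[:-delay]])
        env = _signal.sosfiltfilt(sos_env, env)
        env = np.maximum(env, 0.0)
        envelope[m] = env
        carrier = _bandlimited_noise(n, fs_emg, 20.0, 150.0, rng)
        x = env * carrier
        x += cfg.emg_noise_floor * rng.standard_normal(n)
        x += cfg.drift_amplitude * np.sin(2 * np.pi * 0.3 * t
                                          + rng.uniform(0, 2 * np.pi))
        x += cfg.line_amplitude * np.sin(2 * np.pi * cfg.line_hz * t
                                         + rng.uniform(0, 2 * np.pi))
        emg[m] = np.clip(x, -cfg.emg_max, cfg.emg_max)
    return emg, envelope


def generate_session(cfg: ScenarioConfig, participant_id: int, group: str,
                     rng: np.random.Generator) -> SyntheticSession:
    """One subject's session: all movements, all rounds, concatenated."""
    all_angles, all_imu, all_labels = [], [], []
    offset = 0.0
    for round_id in range(cfg.rounds):
        for movement in cfg.movements:
            series, imu_data, labels = generate_kinematics(
                cfg, movement, rng, round_id=round_id, label_offset=offset)
            all_angles.append(np.vstack([series.roll_phi, series.pitch_theta,
                                         series.yaw_psi]))
            all_imu.append(imu_data)
            all_labels.extend(labels)
            offset += imu_data.shape[1] / cfg.imu_fs
    ang = np.concatenate(all_angles, axis=1)
    imu_data = np.concatenate(all_imu, axis=1)
    n_imu = imu_data.shape[1]
    t_imu = np.arange(n_imu) / cfg.imu_fs
    angles = OrientationSeries(ang[0], ang[1], ang[2], fs=cfg.imu_fs)

    emg_data, envelope = emg_from_kinematics(angles, cfg, rng)
    n_emg = emg_data.shape[1]
    t_emg = np.arange(n_emg) / cfg.emg_fs

    imu = RawRecording(imu_data, cfg.imu_fs, t_imu, list(IMU_CHANNELS), "imu")
    emg = RawRecording(emg_data, cfg.emg_fs, t_emg,
                       list(cfg.emg_channels), "emg")
    return SyntheticSession(imu=imu, emg=emg, angles=angles,
                            envelope=envelope, labels=all_labels,
                            participant_id=participant_id, group=group)


def pathological_variant(session: SyntheticSession, severity: float,
                         rng: np.random.Generator | None = None
                         ) -> SyntheticSession:
    """Inject pathology-like irregularity into a session's EMG.

    Proportionally to ``severity`` in [0, 1]: amplitude dropouts (brief
    near-silent intervals), 4-6 Hz tremor bursts, multiplicative
    envelope jitter, and extra non-stationary noise.  ``severity = 0``
    returns an unchanged copy; movement labels are preserved and the
    group becomes "injured".
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    emg = session.emg.copy()
    env = session.envelope.copy()
    if severity == 0.0:
        return dataclasses.replace(session, emg=emg, envelope=env)
    rng = rng or np.random.default_rng(0)
    fs = emg.fs
    n = emg.n_samples
    duration = n / fs
    env_scale = max(env.max(), 1e-6)
    # event rates per second, proportional to severity
    n_tremor = int(round(0.10 * severity * duration))
    n_dropout = int(round(0.25 * severity * duration))
    sos_jitter = _signal.butter(2, 3.0, btype="lowpass", fs=fs, output="sos")
    for m in range(emg.n_channels):
        # multiplicative envelope jitter (non-stationary, ~sub-3 Hz)
        slow = _signal.sosfiltfilt(sos_jitter, rng.standard_normal(n))
        slow /= max(np.abs(slow).max(), 1e-12)
        jitter = 1.0 + 0.6 * severity * slow
        emg.data[m] *= jitter
        env[m] *= np.abs(jitter)
        # tremor bursts: 4-6 Hz envelope modulation of extra activity,
        # evaluated only on a +-4 sigma slice around each burst center
        for _ in range(n_tremor):
            c = rng.uniform(0.0, duration)
            width = rng.uniform(0.3, 0.8)
            a = max(0, int((c - 4 * width) * fs))
            b = min(n, int((c + 4 * width) * fs))
            ts = np.arange(a, b) / fs
            burst = np.exp(-0.5 * ((ts - c) / width) ** 2)
            f_trem = rng.uniform(4.0, 6.0)
            trem_env = 0.5 * severity * env_scale * burst * (
                0.5 + 0.5 * np.sin(2 * np.pi * f_trem * ts))
            carrier = _bandlimited_noise(b - a, fs, 20.0, 150.0, rng)
            emg.data[m, a:b] += trem_env * carrier
            env[m, a:b] += trem_env
        # amplitude dropouts: brief near-silent intervals
        for _ in range(n_dropout):
            c = rng.uniform(0.0, duration)
            width = rng.uniform(0.1, 0.3)
            a = max(0, int((c - 4 * width) * fs))
            b = min(n, int((c + 4 * width) * fs))
            ts = np.arange(a, b) / fs
            mask = 1.0 - 0.8 * np.exp(-0.5 * ((ts - c) / width) ** 2)
            emg.data[m, a:b] *= mask
            env[m, a:b] *= mask
        emg.data[m] += 0.03 * severity * rng.standard_normal(n)
        np.clip(emg.data[m], -1.5, 1.5, out=emg.data[m])
    return dataclasses.replace(session, emg=emg, envelope=env,
                               group="injured")


# ------------------------------------------------------------- benchmarks

def _session_to_samples(session: SyntheticSession, cfg: ScenarioConfig,
                        L_ms: float = 200.0, S_ms: float = 50.0,
                        filter_spec: FilterSpec | None = None,
                        delta_t: float = 0.005) -> list[WindowedSample]:
    """Run one session through the preprocessing pipeline into samples.

    EMG is band-pass filtered at its native rate, features are computed
    from the native-rate windows (before downsampling), the EMG is then
    block-mean downsampled to the IMU rate and aligned by timestamp.
    """
    spec = filter_spec or FilterSpec(order=4, low_hz=10.0, high_hz=500.0,
                                     fs=cfg.emg_fs)
    emg_f = butterworth_bandpass(session.emg, spec)
    M = int(round(cfg.emg_fs / cfg.imu_fs))
    emg_ds = downsample_mean(emg_f.data, M)
    t_ds = session.emg.timestamps[::M][: emg_ds.shape[1]]
    emg_ds_rec = RawRecording(emg_ds, cfg.imu_fs, t_ds,
                              list(cfg.emg_channels), "emg")
    report = align_streams(emg_ds_rec, session.imu, delta_t=delta_t)

    samples: list[WindowedSample] = []
    fs_ratio = int(round(cfg.emg_fs / cfg.imu_fs))
    for lab in session.labels:
        a = int(round(lab.t_start * cfg.imu_fs))
        b = int(round(lab.t_end * cfg.imu_fs))
        imu_seg = session.imu.data[:, a:b]
        emg_seg = emg_f.data[:, a * fs_ratio:b * fs_ratio]
        env_seg = session.envelope[:, a * fs_ratio:b * fs_ratio]
        wins = segment_windows(
            imu_seg, emg_seg, imu_fs=cfg.imu_fs, emg_fs=cfg.emg_fs,
            L_ms=L_ms, S_ms=S_ms, t0=lab.t_start,
            movement_label=lab.movement_label,
            participant_id=session.participant_id,
            round_id=lab.round_id, repetition=lab.repetition,
            group=session.group)
        for w in wins:
            n_emg = w.emg_window.shape[1]
            feats = np.array([
                extract_features(w.emg_window[c], cfg.emg_fs).as_array()
                for c in range(w.emg_window.shape[0])])
            w.features = feats                                   # (5, 6)
            e0 = int(round((w.start_time - lab.t_start) * cfg.emg_fs))
            seg = env_seg[:, e0:e0 + n_emg]
            w.envelope_rms = np.sqrt(np.mean(seg ** 2, axis=1))
        samples.extend(wins)
    return samples


def make_sessions(cfg: ScenarioConfig) -> list[SyntheticSession]:
    """Generate all subjects' sessions; injured subjects get pathology."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_subjects)
    n_healthy = int(round(cfg.healthy_fraction * cfg.n_subjects))
    sessions = []
    for pid in range(cfg.n_subjects):
        rng = np.random.default_rng(children[pid])
        group = "healthy" if pid < n_healthy else "injured"
        session = generate_session(cfg, pid, "healthy", rng)
        if group == "injured":
            session = pathological_variant(session, cfg.pathology_severity, rng)
        sessions.append(session)
    return sessions


def make_benchmark(task: str, cfg: ScenarioConfig | None = None,
                   split_seed: int = 0, L_ms: float = 200.0,
                   S_ms: float = 50.0) -> DatasetSplit:
    """End-to-end benchmark: generate -> preprocess -> features -> split.

    Runs the full pipeline and returns a normalized, repetition-atomic
    70/20/10 split whose manifest records every seed and parameter.
    """
    if task not in ("classification", "regression", "generation"):
        raise ValueError(f"unknown task {task!r}")
    cfg = cfg or ScenarioConfig()
    samples = []
    for session in make_sessions(cfg):
        samples.extend(_session_to_samples(session, cfg, L_ms=L_ms, S_ms=S_ms))
    split = split_dataset(samples, seed=split_seed)
    stats = fit_normalizer(split.train)
    split = DatasetSplit(
        train=apply_normalizer(stats, split.train),
        val=apply_normalizer(stats, split.val),
        test=apply_normalizer(stats, split.test),
        normalization=stats,
        manifest={**split.manifest, "task": task,
                  "scenario": cfg.to_dict(),
                  "window_ms": {"L": L_ms, "S": S_ms}},
    )
    return split


def generation_sequences(split: DatasetSplit, stride: int = 4) -> dict:
    """Per-repetition feature sequences for the generation task.

    For every repetition, windows are ordered by start time and strided;
    the target at each step is the five-channel window RMS feature,
    z-scored with training-set statistics.  Returns
    ``{"train"|"val"|"test": [(X_seq, Y_seq, meta), ...], "stats": ...}``.
    """
    def group_reps(samples):
        reps: dict[tuple, list[WindowedSample]] = {}
        for s in samples:
            reps.setdefault(s.repetition_key, []).append(s)
        return reps

    train_rms = np.stack([s.features[:, 0] for s in split.train])
    mu, sd = train_rms.mean(axis=0), np.maximum(train_rms.std(axis=0), 1e-8)

    out: dict = {"stats": {"mu": mu, "sd": sd}}
    for name, samples in split.subsets().items():
        seqs = []
        for key, reps in sorted(group_reps(samples).items()):
            reps = sorted(reps, key=lambda s: s.start_time)[::stride]
            X = np.stack([s.imu_window for s in reps])
            Y = np.stack([(s.features[:, 0] - mu) / sd for s in reps])
            meta = {"repetition_key": key, "group": reps[0].group,
                    "movement": reps[0].movement_label}
            seqs.append((X, Y, meta))
        out[name] = seqs
    return out
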