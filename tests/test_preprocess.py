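"""Coordinate transforms, Euler angles, filtering, downsampling, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swctnet.preprocess import (GRAVITY, FilterSpec, RawRecording,
                                align_streams, butterworth_bandpass,
                                butterworth_magnitude_sq,
                                compute_euler_angles, downsample_mean,
                                to_global_frame)

from oracles import downsample_loop


def _imu_recording(data, fs=200.0):
    n = data.shape[1]
    return RawRecording(data, fs, np.arange(n) / fs,
                        [f"c{i}" for i in range(data.shape[0])], "imu")


def _random_rotations(rng, n):
    """Proper rotation matrices via QR decomposition."""
    out = np.empty((n, 3, 3))
    for i in range(n):
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        out[i] = q
    return out


class TestGlobalFrame:
    def test_identity_rotation_is_a_no_op(self):
        rng = np.random.default_rng(0)
        rec = _imu_recording(rng.normal(size=(3, 50)))
        out = to_global_frame(rec, np.tile(np.eye(3), (50, 1, 1)))
        assert np.allclose(out.data, rec.data)

    def test_pi_rotation_about_z_flips_x(self):
        rec = _imu_recording(np.array([[1.0], [0.0], [0.0]]))
        Rz = np.array([[[-1, 0, 0], [0, -1, 0], [0, 0, 1.0]]])
        out = to_global_frame(rec, Rz)
        assert np.allclose(out.data[:, 0], [-1, 0, 0])

    def test_rotation_preserves_norm_per_sample(self):
        rng = np.random.default_rng(1)
        rec = _imu_recording(rng.normal(size=(6, 40)))  # two triads
        R = _random_rotations(rng, 40)
        out = to_global_frame(rec, R)
        for c0 in (0, 3):
            n_in = np.linalg.norm(rec.data[c0:c0 + 3], axis=0)
            n_out = np.linalg.norm(out.data[c0:c0 + 3], axis=0)
            assert np.allclose(n_in, n_out, atol=1e-9)

    def test_non_orthonormal_rotation_rejected(self):
        rec = _imu_recording(np.zeros((3, 2)))
        bad = np.tile(np.eye(3) * 1.01, (2, 1, 1))
        with pytest.raises(ValueError, match="orthonormal"):
            to_global_frame(rec, bad)


class TestEulerAngles:
    def test_rest_pose_gives_zero_angles(self):
        accel = np.array([[0.0], [0.0], [GRAVITY]])
        mag = np.array([[1.0], [0.0], [0.0]])
        s = compute_euler_angles(accel, mag)
        assert s.roll_phi[0] == s.pitch_theta[0] == s.yaw_psi[0] == 0.0

    def test_pitch_at_gravity_along_minus_x(self):
        accel = np.array([[-GRAVITY], [0.0], [1e-12]])
        mag = np.array([[1.0], [0.0]])
        s = compute_euler_angles(accel, mag)
        assert np.isclose(s.pitch_theta[0], np.pi / 2)

    def test_yaw_quarter_turn(self):
        accel = np.array([[0.0], [0.0], [GRAVITY]])
        mag = np.array([[0.0], [1.0]])
        s = compute_euler_angles(accel, mag)
        assert np.isclose(s.yaw_psi[0], np.pi / 2)

    def test_round_trip_away_from_gimbal_lock(self):
        rng = np.random.default_rng(2)
        n = 500
        phi = rng.uniform(-np.pi + 1e-3, np.pi, n)
        theta = rng.uniform(-(np.pi / 2 - 0.1), np.pi / 2 - 0.1, n)
        psi = rng.uniform(-np.pi + 1e-3, np.pi, n)
        accel = np.vstack([-GRAVITY * np.sin(theta),
                           GRAVITY * np.sin(phi) * np.cos(theta),
                           GRAVITY * np.cos(phi) * np.cos(theta)])
        mag = np.vstack([np.cos(psi), np.sin(psi)])
        s = compute_euler_angles(accel, mag)
        assert np.allclose(s.roll_phi, phi, atol=1e-6)
        assert np.allclose(s.pitch_theta, theta, atol=1e-6)
        assert np.allclose(s.yaw_psi, psi, atol=1e-6)
        assert s.n_flagged == 0

    def test_out_of_range_pitch_flagged_nan(self):
        accel = np.array([[-1.5 * GRAVITY, 0.0], [0.0, 0.0],
                          [0.0, GRAVITY]])
        mag = np.ones((2, 2))
        s = compute_euler_angles(accel, mag)
        assert s.n_flagged == 1
        assert np.isnan(s.pitch_theta[0]) and np.isfinite(s.pitch_theta[1])


class TestButterworth:
    def _tone(self, freq, fs=2000.0, seconds=2.0):
        t = np.arange(int(fs * seconds)) / fs
        data = np.sin(2 * np.pi * freq * t)[None, :]
        return RawRecording(data, fs, t, ["emg0"], "emg")

    def test_dc_is_removed(self):
        fs = 2000.0
        rec = RawRecording(np.ones((1, 4000)), fs, np.arange(4000) / fs,
                           ["emg0"], "emg")
        out = butterworth_bandpass(rec, FilterSpec(fs=fs))
        assert np.abs(out.data[:, 500:-500]).max() < 1e-3

    def test_band_center_amplitude_preserved_within_1pct(self):
        rec = self._tone(100.0)
        out = butterworth_bandpass(rec, FilterSpec(fs=2000.0))
        mid = out.data[0, 1000:-1000]
        assert abs(mid.max() - 1.0) < 0.01

    def test_stopband_and_passband_contract(self):
        spec = FilterSpec(order=4, low_hz=10.0, high_hz=500.0, fs=2000.0)
        low = butterworth_bandpass(self._tone(1.0, seconds=4.0), spec)
        ref = butterworth_bandpass(self._tone(100.0, seconds=4.0), spec)
        def level(rec):
            mid = rec.data[0, 2000:-2000]
            return np.sqrt(np.mean(mid ** 2))
        atten_db = 20 * np.log10(level(low) / (1 / np.sqrt(2)))
        pass_db = 20 * np.log10(level(ref) / (1 / np.sqrt(2)))
        assert atten_db <= -20.0
        assert abs(pass_db) <= 1.0

    def test_analog_prototype_half_power_at_cutoff(self):
        for order in (1, 2, 4, 8):
            assert np.isclose(butterworth_magnitude_sq(120.0, 120.0, order), 0.5)
        # -3.01 dB
        db = 10 * np.log10(butterworth_magnitude_sq(120.0, 120.0, 4))
        assert np.isclose(db, -3.0103, atol=1e-3)

    def test_short_signal_error_names_minimum_length(self):
        fs = 2000.0
        rec = RawRecording(np.zeros((1, 10)), fs, np.arange(10) / fs,
                           ["emg0"], "emg")
        with pytest.raises(ValueError, match="minimum"):
            butterworth_bandpass(rec, FilterSpec(fs=fs))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(low_hz=500.0, high_hz=10.0)
        with pytest.raises(ValueError):
            FilterSpec(low_hz=10.0, high_hz=1200.0, fs=2000.0)


class TestDownsample:
    def test_block_means_of_ramp(self):
        out = downsample_mean(np.arange(1.0, 21.0), 10)
        assert np.allclose(out, [5.5, 15.5])

    def test_factor_one_is_identity(self):
        x = np.random.default_rng(3).normal(size=17)
        assert np.allclose(downsample_mean(x, 1), x)

    def test_constant_signal_stays_constant(self):
        assert np.allclose(downsample_mean(np.full(25, 3.25), 7), 3.25)

    def test_trailing_partial_block_dropped(self):
        out = downsample_mean(np.arange(10.0), 4)
        assert out.shape == (2,)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(5, 200)
            M = int(rng.integers(1, n + 1))
            x = rng.normal(size=n)
            assert np.allclose(downsample_mean(x, M), downsample_loop(list(x), M),
                               atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False),
           st.integers(1, 10))
    def test_commutes_with_affine_maps(self, a, c, M):
        x = np.linspace(-1, 1, 30)
        direct = downsample_mean(a * x + c, M)
        after = a * downsample_mean(x, M) + c
        assert np.allclose(direct, after, atol=1e-9)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample_mean(np.arange(5.0), 0)


class TestAlignment:
    def _rec(self, t, modality="imu"):
        data = np.zeros((3 if modality == "imu" else 1, len(t)))
        return RawRecording(data, 200.0, t, ["a", "b", "c"][:data.shape[0]],
                            modality)

    def test_identical_grids_fully_paired(self):
        t = np.arange(100) / 200.0
        rep = align_streams(self._rec(t, "emg"), self._rec(t), delta_t=0.005)
        assert rep.pairs.shape[0] == 100
        assert rep.n_discarded_emg == rep.n_discarded_imu == 0

    def test_offset_beyond_tolerance_errors(self):
        # half-grid shift of 2.5 ms with a 2 ms tolerance: no pair qualifies
        t = np.arange(100) / 200.0
        with pytest.raises(ValueError, match="offset"):
            align_streams(self._rec(t + 0.0025, "emg"), self._rec(t),
                          delta_t=0.002)

    def test_whole_grid_shift_realigns_at_lag(self):
        # a 10 ms shift on a 200 Hz grid (5 ms period) is two whole samples:
        # greedy matching re-pairs emg[i] with imu[i+2] at zero offset
        t = np.arange(100) / 200.0
        rep = align_streams(self._rec(t + 0.010, "emg"), self._rec(t),
                            delta_t=0.005)
        assert rep.pairs.shape[0] == 98
        assert np.all(rep.pairs[:, 1] - rep.pairs[:, 0] == 2)
        assert rep.max_offset == pytest.approx(0.0, abs=1e-12)

    def test_small_offset_fully_paired(self):
        t = np.arange(100) / 200.0
        rep = align_streams(self._rec(t + 0.002, "emg"), self._rec(t),
                            delta_t=0.005)
        assert rep.pairs.shape[0] == 100
        assert rep.max_offset == pytest.approx(0.002)

    def test_pairs_strictly_increasing_in_both_streams(self):
        rng = np.random.default_rng(5)
        te = np.sort(rng.uniform(0, 1, 80))
        te += np.arange(80) * 1e-9  # enforce strict monotonicity
        ti = np.sort(rng.uniform(0, 1, 90))
        ti += np.arange(90) * 1e-9
        rep = align_streams(self._rec(te, "emg"), self._rec(ti), delta_t=0.01)
        assert np.all(np.diff(rep.pairs[:, 0]) > 0)
        assert np.all(np.diff(rep.pairs[:, 1]) > 0)


def test_recording_invariants_enforced():
    t = np.arange(4) / 10.0
    with pytest.raises(ValueError, match="triads"):
        RawRecording(np.zeros((4, 4)), 10.0, t, list("abcd"), "imu")
    with pytest.raises(ValueError, match="increasing"):
        RawRecording(np.zeros((3, 4)), 10.0, t[::-1], list("abc"), "imu")
    with pytest.raises(ValueError):
        RawRecording(np.zeros((3, 4)), -1.0, t, list("abc"), "imu")
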