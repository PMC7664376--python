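import numpy as np
import pytest

import headpdr as hp
from headpdr.heading import (
    EkfResult,
    MahonyState,
    attitude_from_accel,
    estimated_gravity,
    euler_to_quat,
    hasan_ekf,
    magnetic_azimuth,
    mahony_heading,
    mahony_step,
    quat_conj,
    quat_from_axis_angle,
    quat_mul,
    quat_rotate,
    quat_to_euler,
    quat_to_rotmat,
    zhu_heading,
    _euler_rate_matrix,
    _gravity_body,
    _measurement_jacobian,
    _process_jacobian,
)
from headpdr.signal_core import GRAVITY, ImuSequence

from conftest import random_unit_quaternion


def make_seq(gyro, accel, fs=20.0, mag=None):
    n = len(gyro)
    return ImuSequence(
        t=np.arange(n) / fs, accel=accel, gyro=gyro, mag=mag, nominal_rate=fs
    )


class TestQuaternionAlgebra:
    def test_identity_rotmat(self):
        np.testing.assert_allclose(quat_to_rotmat([1, 0, 0, 0]), np.eye(3), atol=1e-15)

    def test_quarter_turn_about_z(self):
        q = np.array([np.cos(np.pi / 4), 0, 0, np.sin(np.pi / 4)])
        np.testing.assert_allclose(quat_to_rotmat(q) @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_orthogonality_and_determinant(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            R = quat_to_rotmat(random_unit_quaternion(rng))
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_rotmat_matches_sandwich_product(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            q = random_unit_quaternion(rng)
            v = rng.normal(size=3)
            np.testing.assert_allclose(quat_to_rotmat(q) @ v, quat_rotate(q, v), atol=1e-12)

    def test_estimated_gravity(self):
        np.testing.assert_allclose(estimated_gravity([1, 0, 0, 0]), [0, 0, 1], atol=1e-15)
        roll_pi = euler_to_quat(np.pi, 0, 0)
        np.testing.assert_allclose(estimated_gravity(roll_pi), [0, 0, -1], atol=1e-12)
        rng = np.random.default_rng(14)
        for _ in range(20):
            q = random_unit_quaternion(rng)
            np.testing.assert_allclose(
                estimated_gravity(q), quat_to_rotmat(q).T @ [0, 0, 1], atol=1e-12
            )

    def test_euler_identity_and_yaw(self):
        np.testing.assert_allclose(quat_to_euler([1, 0, 0, 0]), [0, 0, 0], atol=1e-15)
        q = np.array([np.cos(np.deg2rad(22.5)), 0, 0, np.sin(np.deg2rad(22.5))])
        assert quat_to_euler(q)[2] == pytest.approx(np.deg2rad(45.0), abs=1e-12)

    def test_euler_round_trip_away_from_gimbal_lock(self):
        angles = np.deg2rad(np.array([-170, -85, -30, 0, 30, 85, 170]))
        pitches = np.deg2rad(np.array([-85, -45, 0, 45, 85]))
        for roll in angles:
            for pitch in pitches:
                for yaw in angles:
                    e = quat_to_euler(euler_to_quat(roll, pitch, yaw))
                    np.testing.assert_allclose(e, [roll, pitch, yaw], atol=1e-9)

    def test_attitude_from_accel_inverts_gravity(self):
        q = euler_to_quat(0.2, -0.3, 0.0)
        a = quat_rotate(quat_conj(q), np.array([0, 0, GRAVITY]))
        e = quat_to_euler(attitude_from_accel(a))
        np.testing.assert_allclose(e, [0.2, -0.3, 0.0], atol=1e-9)


class TestMahony:
    def test_aligned_static_state_is_fixed_point(self):
        st = MahonyState(kP=1.0, kI=0.1)
        new = mahony_step(st, np.zeros(3), np.array([0, 0, GRAVITY]), 0.05)
        np.testing.assert_allclose(new.q, st.q, atol=1e-12)

    def test_unit_norm_preserved(self):
        rng = np.random.default_rng(21)
        st = MahonyState(kP=1.0, kI=0.1)
        for _ in range(2000):
            st = mahony_step(st, rng.normal(0, 1, 3), rng.normal(0, 3, 3), 0.05)
            assert abs(np.linalg.norm(st.q) - 1.0) < 1e-9

    def test_static_roll_error_converges(self):
        """10 deg initial roll error decays below 0.1 deg within 10 s at kP=1."""
        st = MahonyState(q=euler_to_quat(np.deg2rad(10), 0, 0), kP=1.0, kI=0.0)
        accel = np.array([0, 0, GRAVITY])
        for _ in range(200):  # 10 s at 20 Hz
            st = mahony_step(st, np.zeros(3), accel, 0.05)
        roll = quat_to_euler(st.q)[0]
        assert abs(np.rad2deg(roll)) < 0.1

    def test_pure_gyro_matches_axis_angle_oracle(self):
        omega, dt, n = 0.7, 0.05, 100
        st = MahonyState(kP=0.0, kI=0.0)
        for _ in range(n):
            st = mahony_step(st, np.array([0, 0, omega]), np.zeros(3), dt)
        got = quat_to_euler(st.q)[2]
        exact = quat_to_euler(quat_from_axis_angle([0, 0, 1], omega * n * dt))[2]
        assert got == pytest.approx(exact, abs=n * (omega * dt) ** 2)

    def test_bias_never_changes_with_zero_integral_gain(self):
        rng = np.random.default_rng(8)
        st = MahonyState(kP=1.0, kI=0.0)
        for _ in range(100):
            st = mahony_step(st, rng.normal(0, 1, 3), rng.normal(0, 2, 3), 0.05)
        np.testing.assert_array_equal(st.bias_hat, np.zeros(3))

    def test_gyro_bias_recovery_on_static_data(self):
        """bias_hat converges to an injected constant bias within 5%."""
        bias = np.array([0.02, -0.015, 0.0])
        err = hp.SensorErrorModel(0.0, 0.0, tuple(bias), 0.0, 0.0, seed=0)
        seq = hp.simulate_static(60.0, np.array([1.0, 0, 0, 0]), err)
        st = MahonyState(kP=1.0, kI=0.3)
        for i in range(len(seq)):
            st = mahony_step(st, seq.gyro[i], seq.accel[i], seq.dt[i])
        np.testing.assert_allclose(st.bias_hat[:2], bias[:2], rtol=0.05)

    def test_static_sequence_yaw_stays_zero(self):
        err = hp.SensorErrorModel.noiseless()
        seq = hp.simulate_static(5.0, np.array([1.0, 0, 0, 0]), err)
        yaw = mahony_heading(seq)
        np.testing.assert_allclose(yaw, 0.0, atol=1e-9)

    def test_simulated_turn_recovered(self, noiseless):
        sc = hp.WalkScenario(
            waypoints=((0.0, 0.0), (10.0, 0.0), (10.0, 10.0)), standstill=2.0
        )
        seq, truth = hp.simulate_walk(sc, noiseless)
        yaw = mahony_heading(seq, q0=attitude_from_accel(seq.accel[:20].mean(axis=0)))
        assert np.rad2deg(yaw[-1]) == pytest.approx(90.0, abs=1.0)

    def test_gyro_sign_flip_negates_yaw(self):
        n = 200
        gyro = np.zeros((n, 3))
        gyro[:, 2] = 0.5 * np.sin(np.arange(n) / 30.0)
        accel = np.tile([0.0, 0.0, GRAVITY], (n, 1))
        seq = make_seq(gyro, accel)
        flipped = make_seq(-gyro, accel)
        np.testing.assert_allclose(
            mahony_heading(flipped), -mahony_heading(seq), atol=1e-9
        )


class TestZhuHeading:
    def test_pure_gyro_integration_limit(self):
        n, fs, omega = 100, 20.0, 0.5
        gyro = np.tile([0.0, 0.0, omega], (n, 1))
        accel = np.tile([0.0, 0.0, GRAVITY], (n, 1))
        mag = np.tile([0.0, 1.0, 0.0], (n, 1))
        seq = make_seq(gyro, accel, fs, mag)
        yaw = zhu_heading(seq, k_gyr=1.0, k_mag=0.0, gyro_threshold=0.05)
        assert yaw[-1] == pytest.approx(omega * n / fs, abs=2 * omega / fs)

    def test_pure_magnetometer_limit_static(self):
        err = hp.SensorErrorModel(0.0, 0.0, (0.0, 0.0, 0.0), 0.0, 0.3, seed=0)
        seq = hp.simulate_static(5.0, euler_to_quat(0, 0, 0.4), err)
        az = magnetic_azimuth(seq)
        np.testing.assert_allclose(az, 0.3 + 0.4, atol=1e-9)
        yaw = zhu_heading(seq, k_gyr=0.0, k_mag=1.0)
        np.testing.assert_allclose(yaw, 0.0, atol=1e-9)

    def test_subthreshold_gyro_is_gated_out(self):
        rng = np.random.default_rng(3)
        n = 200
        gyro = rng.normal(0, 0.01, (n, 3))
        accel = np.tile([0.0, 0.0, GRAVITY], (n, 1))
        mag = np.tile([0.0, 1.0, 0.0], (n, 1))
        seq = make_seq(gyro, accel, mag=mag)
        yaw = zhu_heading(seq, k_gyr=1.0, k_mag=0.0, gyro_threshold=0.05)
        np.testing.assert_allclose(yaw, 0.0, atol=1e-12)

    def test_missing_magnetometer_rejected(self):
        seq = make_seq(np.zeros((10, 3)), np.tile([0.0, 0.0, GRAVITY], (10, 1)))
        with pytest.raises(ValueError, match="magnetometer"):
            zhu_heading(seq)


class TestHasanEkf:
    def test_static_truth_is_fixed_point(self):
        err = hp.SensorErrorModel.noiseless()
        seq = hp.simulate_static(10.0, np.array([1.0, 0, 0, 0]), err)
        res = hasan_ekf(seq, x0=np.zeros(6))
        assert isinstance(res, EkfResult)
        np.testing.assert_allclose(res.euler, 0.0, atol=1e-6)

    def test_initial_pitch_error_converges(self):
        err = hp.SensorErrorModel.noiseless()
        seq = hp.simulate_static(15.0, np.array([1.0, 0, 0, 0]), err)
        x0 = np.zeros(6)
        x0[1] = np.deg2rad(5.0)
        res = hasan_ekf(seq, x0=x0)
        assert abs(np.rad2deg(res.euler[-1, 1])) < 0.5

    def test_innovations_zero_mean_on_matched_data(self):
        """Whiteness: innovation mean within 3 standard errors, 20 seeds."""
        means, ses = [], []
        for seed in range(20):
            err = hp.SensorErrorModel(
                accel_noise_sigma=0.2,
                gyro_noise_sigma=0.01,
                gyro_bias=(0.0, 0.0, 0.0),
                mag_noise_sigma=0.0,
                seed=seed,
            )
            seq = hp.simulate_static(10.0, np.array([1.0, 0, 0, 0]), err)
            nu = hasan_ekf(seq, x0=np.zeros(6)).innovations[20:]
            means.append(nu.mean(axis=0))
            ses.append(nu.std(axis=0) / np.sqrt(nu.shape[0]))
        mean = np.mean(means, axis=0)
        se = np.mean(ses, axis=0) / np.sqrt(20)
        assert np.all(np.abs(mean) < 3 * se)

    def test_jacobians_match_finite_differences(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            theta = rng.uniform(-0.8, 0.8, 3)
            omega = rng.uniform(-1.0, 1.0, 3)
            x = np.concatenate([theta, omega])
            dt = 0.05

            def f(x):
                out = x.copy()
                out[:3] = x[:3] + dt * _euler_rate_matrix(x[0], x[1]) @ x[3:]
                return out

            def h(x):
                return np.concatenate([x[3:], _gravity_body(x[:3], GRAVITY)])

            F = _process_jacobian(theta, omega, dt)
            H = _measurement_jacobian(theta, GRAVITY)
            eps = 1e-7
            for j in range(6):
                dx = np.zeros(6)
                dx[j] = eps
                np.testing.assert_allclose(
                    (f(x + dx) - f(x - dx)) / (2 * eps), F[:, j], atol=1e-6
                )
                np.testing.assert_allclose(
                    (h(x + dx) - h(x - dx)) / (2 * eps), H[:, j], atol=1e-6
                )

    def test_covariance_stays_symmetric_psd(self):
        seq = hp.simulate_static(5.0, np.array([1.0, 0, 0, 0]), hp.SensorErrorModel(seed=1))
        res = hasan_ekf(seq)
        np.testing.assert_allclose(res.P, res.P.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(res.P) > -1e-12)

    def test_non_positive_definite_noise_rejected(self):
        seq = hp.simulate_static(1.0, np.array([1.0, 0, 0, 0]), hp.SensorErrorModel(seed=0))
        with pytest.raises(ValueError, match="positive definite"):
            hasan_ekf(seq, Q=np.zeros((6, 6)))


class TestCrossEstimatorConsistency:
    def test_mahony_tracks_truth_noise_free(self, rectangle_noise_free):
        seq, truth = rectangle_noise_free
        q0 = attitude_from_accel(seq.accel[:40].mean(axis=0))
        yaw = mahony_heading(seq, q0=q0)
        rms = np.sqrt(np.mean((yaw - truth.yaw) ** 2))
        assert np.rad2deg(rms) < 2.0

    def test_mahony_and_ekf_agree_on_clean_turns(self, rectangle_noise_free):
        seq, _ = rectangle_noise_free
        q0 = attitude_from_accel(seq.accel[:40].mean(axis=0))
        ym = mahony_heading(seq, q0=q0)
        x0 = np.concatenate([quat_to_euler(q0), np.zeros(3)])
        ye = hasan_ekf(seq, x0=x0).yaw
        rms = np.sqrt(np.mean((ym - ye) ** 2))
        assert np.rad2deg(rms) < 3.0
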