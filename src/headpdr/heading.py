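"""Attitude and heading estimation for head-mounted IMUs.

Three estimators are provided:

* :func:`mahony_heading` — the explicit complementary filter in unit-
  quaternion form (gyro propagation with a PI correction driven by the
  cross product between the measured and estimated gravity directions).
  Accelerometer + gyroscope only; no magnetometer, by design, because
  low-cost magnetometers suffer unpredictable interference.
* :func:`zhu_heading` — hybrid azimuth: a threshold-gated raw gyro yaw
  integral mixed proportionally with a tilt-compensated magnetic
  azimuth.
* :func:`hasan_ekf` — an extended Kalman filter over Euler angles and
  angular rates, measuring the gyro directly and the accelerometer
  against the gravity prediction.

Conventions: quaternions are scalar-first unit quaternions
``q = (q0, q1, q2, q3)`` representing the body-to-world rotation; Euler
angles are intrinsic Z-Y-X (yaw psi about world z, then pitch theta,
then roll phi), with yaw positive counter-clockwise about the world
z-axis (x/y horizontal, z up).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_core import GRAVITY, ImuSequence

__all__ = [
    "quat_mul",
    "quat_conj",
    "quat_normalize",
    "quat_rotate",
    "quat_from_axis_angle",
    "quat_to_rotmat",
    "estimated_gravity",
    "euler_to_quat",
    "quat_to_euler",
    "attitude_from_accel",
    "MahonyState",
    "mahony_step",
    "mahony_heading",
    "magnetic_azimuth",
    "zhu_heading",
    "EkfResult",
    "hasan_ekf",
]


# ---------------------------------------------------------------- quaternions


def quat_mul(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p (x) q, scalar-first."""
    p0, p1, p2, p3 = p
    q0, q1, q2, q3 = q
    return np.array(
        [
            p0 * q0 - p1 * q1 - p2 * q2 - p3 * q3,
            p0 * q1 + p1 * q0 + p2 * q3 - p3 * q2,
            p0 * q2 - p1 * q3 + p2 * q0 + p3 * q1,
            p0 * q3 + p1 * q2 - p2 * q1 + p3 * q0,
        ]
    )


def quat_conj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(q)
    if n == 0:
        raise ValueError("cannot normalize a zero quaternion")
    return np.asarray(q, dtype=float) / n


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector v by q via the sandwich product q (x) p(v) (x) q*."""
    pv = np.array([0.0, v[0], v[1], v[2]])
    return quat_mul(quat_mul(q, pv), quat_conj(q))[1:]


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def quat_to_rotmat(q: np.ndarray) -> np.ndarray:
    """Orthogonal rotation matrix of the unit quaternion q = a+bi+cj+dk."""
    a, b, c, d = q
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * b * c - 2 * a * d, 2 * b * d + 2 * a * c],
            [2 * b * c + 2 * a * d, a * a - b * b + c * c - d * d, 2 * c * d - 2 * a * b],
            [2 * b * d - 2 * a * c, 2 * c * d + 2 * a * b, a * a - b * b - c * c + d * d],
        ]
    )


def estimated_gravity(q: np.ndarray) -> np.ndarray:
    """Estimated gravity direction R(q)^T (0,0,1) in the body frame."""
    a, b, c, d = q
    return np.array(
        [2 * b * d - 2 * a * c, 2 * c * d + 2 * a * b, a * a - b * b - c * c + d * d]
    )


def euler_to_quat(roll: float, pitch: float, yaw: float) -> np.ndarray:
    """Unit quaternion from intrinsic Z-Y-X Euler angles (rad)."""
    qz = quat_from_axis_angle([0, 0, 1], yaw)
    qy = quat_from_axis_angle([0, 1, 0], pitch)
    qx = quat_from_axis_angle([1, 0, 0], roll)
    return quat_mul(quat_mul(qz, qy), qx)


def quat_to_euler(q: np.ndarray) -> np.ndarray:
    """(roll, pitch, yaw) in rad; the asin argument is clamped to [-1, 1]."""
    q0, q1, q2, q3 = q
    roll = np.arctan2(2 * (q0 * q1 + q2 * q3), 1 - 2 * (q1 * q1 + q2 * q2))
    pitch = np.arcsin(np.clip(2 * (q0 * q2 - q1 * q3), -1.0, 1.0))
    yaw = np.arctan2(2 * (q0 * q3 + q1 * q2), 1 - 2 * (q2 * q2 + q3 * q3))
    return np.array([roll, pitch, yaw])


def attitude_from_accel(accel: np.ndarray) -> np.ndarray:
    """Roll/pitch attitude (yaw = 0) consistent with a static accel reading.

    Trajectories are reported in a walk-relative frame, so the initial
    yaw is defined as zero and only the tilt is recovered from the mean
    specific force during the initial standstill.
    """
    v = np.asarray(accel, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero accelerometer vector cannot define an attitude")
    v = v / n
    roll = np.arctan2(v[1], v[2])
    pitch = -np.arcsin(np.clip(v[0], -1.0, 1.0))
    return euler_to_quat(roll, pitch, 0.0)


# -------------------------------------------------------------------- Mahony


@dataclass
class MahonyState:
    """State of the explicit complementary filter.

    The integral-error accumulator doubles as the gyro-bias estimate:
    the correction term ``kI * err_integral`` added to the measured rate
    is exactly ``-bias_hat``, so ``bias_hat = -kI * err_integral``
    converges to the true gyro bias on static data.
    """

    q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    err_integral: np.ndarray = field(default_factory=lambda: np.zeros(3))
    kP: float = 1.0
    kI: float = 0.1

    def __post_init__(self) -> None:
        if self.kP < 0 or self.kI < 0:
            raise ValueError("gains must be non-negative")
        self.q = quat_normalize(np.asarray(self.q, dtype=float))
        self.err_integral = np.asarray(self.err_integral, dtype=float)

    @property
    def bias_hat(self) -> np.ndarray:
        """Estimated gyro bias (rad/s)."""
        return -self.kI * self.err_integral


def mahony_step(
    state: MahonyState, gyro: np.ndarray, accel: np.ndarray, dt: float
) -> MahonyState:
    """One explicit-complementary-filter update.

    The measured gravity direction v = a/|a| is compared with the
    direction estimated from the quaternion; their cross product e is
    the correction, applied proportionally (kP) and through the
    dt-scaled integral accumulator (kI). A zero-norm accelerometer
    sample skips the correction (pure gyro propagation).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    gyro = np.asarray(gyro, dtype=float)
    accel = np.asarray(accel, dtype=float)
    err_integral = state.err_integral
    a_norm = np.linalg.norm(accel)
    if a_norm > 0:
        v = accel / a_norm
        v_hat = estimated_gravity(state.q)
        e = np.cross(v, v_hat)
        if state.kI > 0:
            err_integral = err_integral + e * dt
        omega = gyro + state.kP * e + state.kI * err_integral
    else:
        omega = gyro
    q_dot = 0.5 * quat_mul(state.q, np.concatenate([[0.0], omega]))
    q = quat_normalize(state.q + q_dot * dt)
    return replace(state, q=q, err_integral=err_integral)


def mahony_heading(
    seq: ImuSequence,
    kP: float = 1.0,
    kI: float = 0.1,
    q0: np.ndarray | None = None,
    unwrap: bool = True,
    return_state: bool = False,
):
    """Yaw series (rad) from folding the Mahony filter over a sequence.

    If ``q0`` is None the filter starts at the identity. Yaw is
    accumulated continuously (unwrapped) by default so step-and-heading
    integration never sees a 2*pi jump.
    """
    state = MahonyState(q=q0 if q0 is not None else np.array([1.0, 0, 0, 0]), kP=kP, kI=kI)
    dts = seq.dt
    yaw = np.empty(len(seq))
    for i in range(len(seq)):
        state = mahony_step(state, seq.gyro[i], seq.accel[i], dts[i])
        yaw[i] = quat_to_euler(state.q)[2]
    if unwrap:
        yaw = np.unwrap(yaw)
    if return_state:
        return yaw, state
    return yaw


# ------------------------------------------------------------------ Zhu 2018


def magnetic_azimuth(seq: ImuSequence) -> np.ndarray:
    """Tilt-compensated magnetic azimuth series (rad, unwrapped).

    Roll and pitch are taken from the per-sample accelerometer reading;
    the magnetometer vector is de-rotated to the horizontal plane and
    the azimuth increases with counter-clockwise yaw, offset by the
    local field declination (which cancels when the series is
    referenced to its initial value).
    """
    if not seq.has_mag:
        raise ValueError("magnetic azimuth requires magnetometer data")
    az = np.empty(len(seq))
    for i in range(len(seq)):
        a = seq.accel[i]
        n = np.linalg.norm(a)
        if n == 0:
            roll, pitch = 0.0, 0.0
        else:
            v = a / n
            roll = np.arctan2(v[1], v[2])
            pitch = -np.arcsin(np.clip(v[0], -1.0, 1.0))
        # de-rotate mag into the level frame: h = Ry(pitch) Rx(roll) m
        q_tilt = euler_to_quat(roll, pitch, 0.0)
        h = quat_rotate(q_tilt, seq.mag[i])
        az[i] = np.arctan2(h[0], h[1])
    return np.unwrap(az)


def zhu_heading(
    seq: ImuSequence,
    k_gyr: float = 0.9,
    k_mag: float = 0.1,
    gyro_threshold: float = 0.05,
) -> np.ndarray:
    """Hybrid gyro/magnetometer yaw series (rad).

    The gyro yaw is the cumulative integral of the body z-rate, applied
    only on samples whose gyro norm exceeds ``gyro_threshold`` (rad/s);
    the magnetic azimuth is referenced to its initial value so both
    terms share an origin. Output is ``k_gyr * phi_gyr + k_mag *
    phi_mag``, in the same convention as :func:`mahony_heading`
    (walk-relative, starting at zero).
    """
    if not seq.has_mag:
        raise ValueError("zhu_heading requires magnetometer data")
    dts = seq.dt
    rates = np.where(np.linalg.norm(seq.gyro, axis=1) > gyro_threshold, seq.gyro[:, 2], 0.0)
    phi_gyr = np.cumsum(rates * dts)
    phi_mag = magnetic_azimuth(seq)
    phi_mag = phi_mag - phi_mag[0]
    return k_gyr * phi_gyr + k_mag * phi_mag


# ----------------------------------------------------------------- Hasan EKF


def _euler_rate_matrix(roll: float, pitch: float) -> np.ndarray:
    """E(phi, theta) mapping body rates to Euler-angle rates (Z-Y-X)."""
    sphi, cphi = np.sin(roll), np.cos(roll)
    ct = np.cos(pitch)
    tt = np.tan(pitch)
    return np.array(
        [
            [1.0, sphi * tt, cphi * tt],
            [0.0, cphi, -sphi],
            [0.0, sphi / ct, cphi / ct],
        ]
    )


def _process_jacobian(theta: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """F = I + dt * d f / d x for f = [E(theta) omega; 0]."""
    roll, pitch = theta[0], theta[1]
    p, q, r = omega
    sphi, cphi = np.sin(roll), np.cos(roll)
    ct = np.cos(pitch)
    st = np.sin(pitch)
    tt = st / ct
    d_theta = np.array(
        [
            [(cphi * q - sphi * r) * tt, (sphi * q + cphi * r) / ct**2, 0.0],
            [-sphi * q - cphi * r, 0.0, 0.0],
            [(cphi * q - sphi * r) / ct, (sphi * q + cphi * r) * st / ct**2, 0.0],
        ]
    )
    F = np.eye(6)
    F[:3, :3] += dt * d_theta
    F[:3, 3:] = dt * _euler_rate_matrix(roll, pitch)
    return F


def _gravity_body(theta: np.ndarray, g: float) -> np.ndarray:
    """Accelerometer prediction R(theta)^T (0,0,g) for a static sensor."""
    roll, pitch = theta[0], theta[1]
    return g * np.array(
        [-np.sin(pitch), np.sin(roll) * np.cos(pitch), np.cos(roll) * np.cos(pitch)]
    )


def _measurement_jacobian(theta: np.ndarray, g: float) -> np.ndarray:
    """H for h(x) = [omega; R(theta)^T (0,0,g)]."""
    roll, pitch = theta[0], theta[1]
    sphi, cphi = np.sin(roll), np.cos(roll)
    st, ct = np.sin(pitch), np.cos(pitch)
    H = np.zeros((6, 6))
    H[:3, 3:] = np.eye(3)
    H[3:, :3] = g * np.array(
        [
            [0.0, -ct, 0.0],
            [cphi * ct, -sphi * st, 0.0],
            [-sphi * ct, -cphi * st, 0.0],
        ]
    )
    return H


@dataclass
class EkfResult:
    """Euler-angle trace and diagnostics of an EKF run."""

    euler: np.ndarray  # (n, 3) roll, pitch, yaw in rad (yaw unwrapped)
    innovations: np.ndarray  # (n, 6) measurement residuals
    P: np.ndarray  # final 6x6 covariance

    @property
    def yaw(self) -> np.ndarray:
        return self.euler[:, 2]


def hasan_ekf(
    seq: ImuSequence,
    Q: np.ndarray | None = None,
    R: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    P0: np.ndarray | None = None,
    g: float = GRAVITY,
) -> EkfResult:
    """Extended Kalman filter over x = [roll, pitch, yaw, wx, wy, wz].

    Process model: Euler-rate kinematics ``theta_dot = E(theta) omega``
    with a constant-rate assumption ``omega_dot = 0``, discretised at
    the per-sample dt. Measurement model: the gyro observes omega
    directly and the accelerometer observes the body-frame gravity
    ``R(theta)^T (0,0,g)``. Jacobians are analytic. The covariance is
    re-symmetrised after every update as a numerical safeguard.

    Q and R default to diagonals sized for low-cost MEMS noise
    (gyro sigma 0.01 rad/s, accel sigma 0.2 m/s^2).
    """
    n = len(seq)
    dts = seq.dt
    if Q is None:
        Q = np.diag([1e-6] * 3 + [2.5e-3] * 3)
    if R is None:
        R = np.diag([1e-4] * 3 + [4e-2] * 3)
    Q = np.asarray(Q, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(np.linalg.eigvalsh(Q) <= 0) or np.any(np.linalg.eigvalsh(R) <= 0):
        raise ValueError("Q and R must be positive definite")
    x = np.zeros(6) if x0 is None else np.asarray(x0, dtype=float).copy()
    P = np.diag([1e-2] * 3 + [1e-2] * 3) if P0 is None else np.asarray(P0, dtype=float).copy()

    euler = np.empty((n, 3))
    innov = np.empty((n, 6))
    I6 = np.eye(6)
    for i in range(n):
        dt = dts[i]
        # predict
        theta, omega = x[:3], x[3:]
        x = x.copy()
        x[:3] = theta + dt * _euler_rate_matrix(theta[0], theta[1]) @ omega
        F = _process_jacobian(theta, omega, dt)
        P = F @ P @ F.T + Q
        # update
        y = np.concatenate([seq.gyro[i], seq.accel[i]])
        h = np.concatenate([x[3:], _gravity_body(x[:3], g)])
        H = _measurement_jacobian(x[:3], g)
        S = H @ P @ H.T + R
        K = np.linalg.solve(S.T, (P @ H.T).T).T
        nu = y - h
        x = x + K @ nu
        P = (I6 - K @ H) @ P
        P = 0.5 * (P + P.T)
        euler[i] = x[:3]
        innov[i] = nu
    euler[:, 2] = np.unwrap(euler[:, 2])
    return EkfResult(euler=euler, innovations=innov, P=P)
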