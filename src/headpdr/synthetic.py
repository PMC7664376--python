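"""Synthetic head-mounted IMU walking simulator with full ground truth.

Generates accelerometer/gyroscope/magnetometer streams for a
parameterised walk along a waypoint path, emulating the standard data-
collection protocol for head-mounted step-and-heading experiments:
stand still for 5 s, walk at constant cadence with the head facing the
walking direction, stand still for 5 s. The default path is a
25.5 m x 8.5 m rectangle (68 m perimeter) sampled at 20 Hz.

Signal model
------------
* One vertical specific-force oscillation per step (the centre of mass
  rises and falls once per step), so the accelerometer-norm extrema are
  exactly ``g +- osc_amplitude`` and the noise-free norm has exactly one
  peak per ground-truth step.
* Heading follows the path tangent; corners are blended at a bounded
  turn rate so the yaw series has no discontinuities.
* A small gait-synchronised pitch sway (head nod) at the step frequency,
  because a rigidly yaw-only head would leave the gyroscope silent on
  straight segments, which no real head-mounted recording does.
* Gyro samples are the exact discrete rates carrying the attitude from
  one sample to the next, so an independent quaternion integration of
  the noise-free gyro reproduces the ground-truth orientation.
* Sensor errors: i.i.d. Gaussian noise per axis, a constant per-trial
  gyro bias, and a horizontal magnetic field at a fixed declination.
  Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heading import euler_to_quat, quat_conj, quat_mul, quat_rotate
from .signal_core import GRAVITY, ImuSequence
from .stepdetect import StepEvent
from .trajectory import StepVector, Trajectory, integrate_steps

__all__ = [
    "WalkScenario",
    "SensorErrorModel",
    "WalkTruth",
    "simulate_walk",
    "simulate_static",
    "default_rectangle",
    "straight_line",
]


@dataclass(frozen=True)
class WalkScenario:
    """Ground-truth walk parameters.

    waypoints : polyline the walker follows, metres.
    step_length : m per step (0.5 m default, a relaxed adult step).
    step_frequency : steps per second (1.8 Hz default, normal cadence).
    standstill : seconds of standing at the start and end (5 s default).
    osc_amplitude : vertical specific-force oscillation, m/s^2.
    forward_osc_amplitude : fore-aft specific-force oscillation along
        the walking direction, m/s^2, in quadrature with the vertical
        one (the head accelerates and brakes once per step). Must stay
        below ~2 m/s^2 so the norm extrema remain g +- osc_amplitude.
    turn_rate : maximum heading rate at corners, rad/s (45 deg/s).
    sample_rate : IMU sampling rate, Hz.
    sway_amplitude : gait-synchronised head pitch sway, rad (3 deg).
    """

    waypoints: tuple[tuple[float, float], ...]
    step_length: float = 0.5
    step_frequency: float = 1.8
    standstill: float = 5.0
    osc_amplitude: float = 2.0
    forward_osc_amplitude: float = 1.5
    turn_rate: float = np.deg2rad(45.0)
    sample_rate: float = 20.0
    sway_amplitude: float = np.deg2rad(3.0)

    def __post_init__(self) -> None:
        if not 0.5 < self.step_frequency < 3.5:
            raise ValueError("step_frequency must lie in (0.5, 3.5) Hz")
        if self.sample_rate < 4.0 * self.step_frequency:
            raise ValueError("sample_rate must be at least 4x the step frequency")
        if len(self.waypoints) < 2:
            raise ValueError("a walk needs at least two waypoints")
        pts = np.asarray(self.waypoints, dtype=float)
        if np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)) <= 0:
            raise ValueError("degenerate path: zero total length")


@dataclass(frozen=True)
class SensorErrorModel:
    """Additive sensor errors; identical seed means bit-identical output.

    Defaults emulate a low-cost MEMS module after routine calibration:
    0.2 m/s^2 accel noise, 0.01 rad/s gyro noise with a small constant
    per-trial bias, and magnetometer direction noise at 15% of the field
    magnitude.
    """

    accel_noise_sigma: float = 0.2
    gyro_noise_sigma: float = 0.01
    gyro_bias: tuple[float, float, float] = (0.002, -0.002, 0.001)
    mag_noise_sigma: float = 0.15
    mag_declination: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.accel_noise_sigma, self.gyro_noise_sigma, self.mag_noise_sigma) < 0:
            raise ValueError("noise sigmas must be non-negative")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "SensorErrorModel":
        """Zero noise and zero bias; useful as a ground-truth check."""
        return cls(0.0, 0.0, (0.0, 0.0, 0.0), 0.0, 0.0, seed)


@dataclass
class WalkTruth:
    """Everything the simulator knows about the walk it generated."""

    trajectory: Trajectory  # per-step ground-truth positions
    step_events: list[StepEvent]  # ground-truth steps (peak sample/time)
    yaw: np.ndarray  # per-sample ground-truth yaw, rad, unwrapped
    pitch: np.ndarray  # per-sample ground-truth pitch, rad
    step_headings: np.ndarray  # per-step forward direction, rad
    step_length: float
    scenario: WalkScenario

    @property
    def n_steps(self) -> int:
        return len(self.step_events)

    @property
    def total_length(self) -> float:
        return self.step_length * self.n_steps


def _wrap_pi(a: float) -> float:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _step_headings(scenario: WalkScenario) -> np.ndarray:
    """Per-step forward directions along the waypoint polyline.

    Edge headings are unwrapped so consecutive edges differ by the
    minimal turn; corner turns are spread over enough steps that the
    per-step heading change never exceeds turn_rate / step_frequency.
    """
    pts = np.asarray(scenario.waypoints, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 0
    seg, seg_len = seg[keep], seg_len[keep]
    headings = np.arctan2(seg[:, 0], seg[:, 1])  # from +y axis toward +x
    # unwrap so each corner takes the minimal turn
    for i in range(1, len(headings)):
        headings[i] = headings[i - 1] + _wrap_pi(headings[i] - headings[i - 1])
    counts = np.maximum(1, np.round(seg_len / scenario.step_length).astype(int))
    h = np.repeat(headings, counts)
    max_per_step = scenario.turn_rate / scenario.step_frequency
    boundaries = np.cumsum(counts)[:-1]
    last_end = 0
    for b, before, after in zip(boundaries, headings[:-1], headings[1:]):
        delta = after - before
        if delta == 0.0:
            continue
        m = int(np.ceil(abs(delta) / max_per_step))
        s = b - m // 2
        if s < last_end or s + m > len(h):
            raise ValueError("path edges too short to blend corners at this turn rate")
        h[s : s + m] = before + delta * (np.arange(1, m + 1)) / (m + 1)
        last_end = s + m
    return h


def simulate_walk(
    scenario: WalkScenario, err: SensorErrorModel = SensorErrorModel()
) -> tuple[ImuSequence, WalkTruth]:
    """Simulate one walk; returns the sensor stream and its ground truth."""
    g = GRAVITY
    f = scenario.step_frequency
    fs = scenario.sample_rate
    dt = 1.0 / fs

    head = _step_headings(scenario)
    n_steps = head.shape[0]
    yaw_steps = np.pi / 2.0 - head  # estimator yaw convention (ccw from +x)

    t_lead = scenario.standstill
    t_walk = n_steps / f
    total = t_lead + t_walk + scenario.standstill
    n = int(round(total * fs)) + 1
    t = np.arange(n) * dt

    # ground-truth yaw: piecewise linear through mid-step knots
    knots_t = np.concatenate([[0.0], t_lead + (np.arange(n_steps) + 0.5) / f, [total]])
    knots_y = np.concatenate([[yaw_steps[0]], yaw_steps, [yaw_steps[-1]]])
    yaw = np.interp(t, knots_t, knots_y)

    # gait-synchronised pitch sway, zero outside the walking interval
    tau = t - t_lead
    walking = (tau >= 0.0) & (tau <= t_walk)
    pitch = np.where(walking, scenario.sway_amplitude * np.sin(2 * np.pi * f * tau), 0.0)

    quats = [euler_to_quat(0.0, pitch[i], yaw[i]) for i in range(n)]

    # exact discrete body rates: q_{i+1} = q_i (x) exp(omega dt / 2)
    gyro = np.zeros((n, 3))
    for i in range(n - 1):
        dq = quat_mul(quat_conj(quats[i]), quats[i + 1])
        if dq[0] < 0:
            dq = -dq
        vec = dq[1:]
        s = np.linalg.norm(vec)
        angle = 2.0 * np.arctan2(s, dq[0])
        if s > 0:
            gyro[i] = (angle / dt) * vec / s

    # world-frame specific force: gravity plus one vertical peak per
    # step, with a quadrature fore-aft component along the walking
    # direction; the norm extrema remain exactly g +- osc_amplitude
    fz = np.where(walking, g + scenario.osc_amplitude * np.sin(2 * np.pi * f * tau), g)
    fwd = np.where(
        walking, scenario.forward_osc_amplitude * np.cos(2 * np.pi * f * tau), 0.0
    )
    heading_t = np.pi / 2.0 - yaw
    accel = np.empty((n, 3))
    mag = np.empty((n, 3))
    m_world = np.array(
        [np.sin(err.mag_declination), np.cos(err.mag_declination), 0.0]
    )
    for i in range(n):
        qc = quat_conj(quats[i])
        f_world = np.array(
            [fwd[i] * np.sin(heading_t[i]), fwd[i] * np.cos(heading_t[i]), fz[i]]
        )
        accel[i] = quat_rotate(qc, f_world)
        mag[i] = quat_rotate(qc, m_world)

    rng = np.random.default_rng(err.seed)
    if err.accel_noise_sigma > 0:
        accel = accel + rng.normal(0.0, err.accel_noise_sigma, (n, 3))
    gyro = gyro + np.asarray(err.gyro_bias, dtype=float)
    if err.gyro_noise_sigma > 0:
        gyro = gyro + rng.normal(0.0, err.gyro_noise_sigma, (n, 3))
    if err.mag_noise_sigma > 0:
        mag = mag + rng.normal(0.0, err.mag_noise_sigma, (n, 3))

    seq = ImuSequence(t=t, accel=accel, gyro=gyro, mag=mag, nominal_rate=fs)

    # ground truth: step events at the vertical-oscillation peaks
    peak_times = t_lead + (np.arange(n_steps) + 0.25) / f
    events = [
        StepEvent(peak_index=int(round(pt * fs)), peak_time=float(pt))
        for pt in peak_times
    ]
    steps = [StepVector(scenario.step_length, float(hh)) for hh in head]
    truth_traj = integrate_steps(
        tuple(np.asarray(scenario.waypoints[0], dtype=float)), steps, step_times=peak_times
    )
    truth = WalkTruth(
        trajectory=truth_traj,
        step_events=events,
        yaw=yaw,
        pitch=pitch,
        step_headings=head,
        step_length=scenario.step_length,
        scenario=scenario,
    )
    return seq, truth


def simulate_static(
    duration: float,
    attitude: np.ndarray,
    err: SensorErrorModel = SensorErrorModel(),
    sample_rate: float = 20.0,
) -> ImuSequence:
    """Constant-attitude stream (filter-convergence fixture).

    ``attitude`` is the body-to-world unit quaternion; the accelerometer
    reads the body-frame gravity reaction plus noise, the gyro reads
    bias plus noise.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) * (1.0 / sample_rate)
    qc = quat_conj(np.asarray(attitude, dtype=float))
    a_body = quat_rotate(qc, np.array([0.0, 0.0, GRAVITY]))
    m_world = np.array([np.sin(err.mag_declination), np.cos(err.mag_declination), 0.0])
    m_body = quat_rotate(qc, m_world)
    rng = np.random.default_rng(err.seed)
    accel = np.tile(a_body, (n, 1))
    gyro = np.tile(np.asarray(err.gyro_bias, dtype=float), (n, 1))
    mag = np.tile(m_body, (n, 1))
    if err.accel_noise_sigma > 0:
        accel = accel + rng.normal(0.0, err.accel_noise_sigma, (n, 3))
    if err.gyro_noise_sigma > 0:
        gyro = gyro + rng.normal(0.0, err.gyro_noise_sigma, (n, 3))
    if err.mag_noise_sigma > 0:
        mag = mag + rng.normal(0.0, err.mag_noise_sigma, (n, 3))
    return ImuSequence(t=t, accel=accel, gyro=gyro, mag=mag, nominal_rate=sample_rate)


def default_rectangle(**overrides) -> WalkScenario:
    """The benchmark path: a 25.5 m x 8.5 m rectangle (68 m perimeter),
    walked counter-clockwise starting along the long side (+x), with 5 s
    standstills and a 20 Hz sample rate."""
    params = dict(
        waypoints=((0.0, 0.0), (25.5, 0.0), (25.5, 8.5), (0.0, 8.5), (0.0, 0.0)),
    )
    params.update(overrides)
    return WalkScenario(**params)


def straight_line(
    length: float,
    step_length: float = 0.5,
    step_frequency: float = 1.8,
    **overrides,
) -> WalkScenario:
    """A straight walk along +x, e.g. for step-length calibration."""
    return WalkScenario(
        waypoints=((0.0, 0.0), (length, 0.0)),
        step_length=step_length,
        step_frequency=step_frequency,
        **overrides,
    )
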