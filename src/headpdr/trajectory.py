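"""Step-and-heading trajectory integration, metrics and full pipelines.

A step-and-heading system chains per-step displacement vectors: given
the position after the k-th step, the next position is

    x_{k+1} = x_k + l_{k+1} * sin(phi_{k+1})
    y_{k+1} = y_k + l_{k+1} * cos(phi_{k+1})

where l is the step length (m) and phi the step's forward direction,
measured from the +y axis towards +x. Estimator yaw (counter-clockwise
about z from +x, starting at 0 in the walk-relative frame) maps to this
convention as ``phi = pi/2 - yaw``, i.e. the initial walking direction
points along +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heading import attitude_from_accel, hasan_ekf, mahony_heading, zhu_heading
from .signal_core import FilterSpec, ImuSequence, accel_norm, lowpass
from .stepdetect import DetectorConfig, StepEvent, detect_steps, step_windows
from .steplength import (
    DEFAULT_WEINBERG_K,
    ModelCoefficients,
    extract_features,
    predict,
)

__all__ = [
    "StepVector",
    "Trajectory",
    "integrate_steps",
    "heading_per_step",
    "yaw_to_heading",
    "end_to_end_error",
    "total_distance_error",
    "PipelineConfig",
    "run_pipeline",
]

METHODS = ("proposed", "zhu", "hasan")


@dataclass(frozen=True)
class StepVector:
    """One step: length (m, non-negative) and forward direction (rad)."""

    length: float
    heading: float

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("step length must be non-negative")


@dataclass
class Trajectory:
    """Integrated 2-D positions; one more position than steps."""

    positions: np.ndarray  # (n_steps + 1, 2)
    step_times: np.ndarray | None = None  # (n_steps,) seconds

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.step_times is not None:
            self.step_times = np.asarray(self.step_times, dtype=float)
            if self.step_times.shape[0] != self.positions.shape[0] - 1:
                raise ValueError("need one more position than step times")

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0] - 1

    @property
    def length(self) -> float:
        """Polyline length: the sum of per-step segment lengths."""
        if self.positions.shape[0] < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.positions, axis=0), axis=1)))


def integrate_steps(
    start: tuple[float, float],
    steps: list[StepVector],
    step_times: np.ndarray | None = None,
) -> Trajectory:
    """Chain step vectors from a start point into a trajectory."""
    pos = np.empty((len(steps) + 1, 2))
    pos[0] = start
    for k, s in enumerate(steps):
        pos[k + 1, 0] = pos[k, 0] + s.length * np.sin(s.heading)
        pos[k + 1, 1] = pos[k, 1] + s.length * np.cos(s.heading)
    return Trajectory(positions=pos, step_times=step_times)


def heading_per_step(yaw_series: np.ndarray, events: list[StepEvent]) -> np.ndarray:
    """Yaw sampled at each step's peak instant."""
    yaw = np.asarray(yaw_series, dtype=float)
    return np.array([yaw[e.peak_index] for e in events])


def yaw_to_heading(yaw: np.ndarray | float) -> np.ndarray | float:
    """Map estimator yaw (ccw from +x) to the step heading convention.

    Walk-relative frames start at yaw 0, which corresponds to walking
    along +x, i.e. heading pi/2 from the +y axis.
    """
    return np.pi / 2.0 - np.asarray(yaw, dtype=float)


def end_to_end_error(traj: Trajectory) -> float:
    """Distance between the trajectory's own start and end points (m).

    Meaningful as an error on a closed ground-truth loop, where a
    perfect estimate returns to its start.
    """
    if traj.positions.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))


def total_distance_error(real_length: float, traj: Trajectory) -> tuple[float, float]:
    """Absolute and percentage difference of true vs estimated path length."""
    if real_length <= 0:
        raise ValueError("real_length must be positive")
    abs_err = abs(real_length - traj.length)
    return abs_err, 100.0 * abs_err / real_length


# ------------------------------------------------------------------ pipelines


@dataclass
class PipelineConfig:
    """Everything tunable in the three step-and-heading pipelines."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    # step-length coefficients per method
    weinberg: ModelCoefficients = field(
        default_factory=lambda: ModelCoefficients("weinberg", {"k": DEFAULT_WEINBERG_K})
    )
    zhu_length: ModelCoefficients | None = None
    # Hasan's pipeline historically borrows population-level linear
    # coefficients rather than calibrating per subject.
    hasan_linear: ModelCoefficients = field(
        default_factory=lambda: ModelCoefficients("linear", {"a": 0.30, "b": 0.10})
    )
    # Mahony gains
    kP: float = 1.0
    kI: float = 0.1
    # Zhu heading
    k_gyr: float = 0.9
    k_mag: float = 0.1
    gyro_threshold: float = 0.05
    # EKF noise diagonals (None -> estimator defaults)
    ekf_Q: np.ndarray | None = None
    ekf_R: np.ndarray | None = None
    # initial-standstill window used to level the attitude estimate (s)
    init_standstill: float = 2.0
    # cap on a step window's total span, as a multiple of the median
    # inter-peak interval: a step spans one gait period, and without the
    # cap the first and last windows swallow the standstills
    max_window_factor: float = 1.0
    start: tuple[float, float] = (0.0, 0.0)


def _initial_attitude(seq: ImuSequence, window_s: float) -> np.ndarray:
    n = max(1, int(round(window_s * seq.fs)))
    return attitude_from_accel(seq.accel[: min(n, len(seq))].mean(axis=0))


def _clamp_windows(events: list[StepEvent], fs: float, factor: float) -> list[StepEvent]:
    """Bound each step window to peak +- factor/2 median inter-peak spans.

    The midpoint windowing rule lets the first and last windows extend
    into the standstill periods, which would corrupt duration-based
    features; clamping restores physically plausible step spans.
    """
    if len(events) < 2 or factor <= 0:
        return events
    period = float(np.median(np.diff([e.peak_index for e in events])))
    half = max(1, int(round(0.5 * factor * period)))
    out = []
    for e in events:
        s, t = e.window
        s = max(s, e.peak_index - half)
        t = min(t, e.peak_index + half + 1)
        out.append(StepEvent(peak_index=e.peak_index, peak_time=e.peak_time, window=(s, t)))
    return out


def run_pipeline(
    seq: ImuSequence,
    method: str = "proposed",
    config: PipelineConfig | None = None,
) -> Trajectory:
    """Run one of the three step-and-heading pipelines on an IMU stream.

    * ``proposed`` — low-pass filter, peak detection, Weinberg step
      length, Mahony quaternion heading.
    * ``zhu`` — peak detection, hybrid step-length model, hybrid
      gyro/magnetometer azimuth (requires magnetometer data).
    * ``hasan`` — peak detection, linear step-length model, EKF heading.

    Deterministic given the input and configuration.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    cfg = config if config is not None else PipelineConfig()
    if method == "zhu" and not seq.has_mag:
        raise ValueError("zhu pipeline requires magnetometer data")
    if method == "zhu" and cfg.zhu_length is None:
        raise ValueError("zhu pipeline requires calibrated zhu_length coefficients")

    norm = accel_norm(seq)
    filtered = lowpass(norm, seq.fs, cfg.filter_spec, dt=seq.dt)
    events = detect_steps(filtered, seq.fs, cfg.detector, t=seq.t)
    if not events:
        return Trajectory(positions=np.array([cfg.start]), step_times=np.empty(0))
    events = _clamp_windows(step_windows(events, len(seq)), seq.fs, cfg.max_window_factor)

    feats = [extract_features(filtered[s:e], seq.fs) for s, e in (ev.window for ev in events)]
    if method == "proposed":
        coeffs = cfg.weinberg
        q0 = _initial_attitude(seq, cfg.init_standstill)
        yaw = mahony_heading(seq, kP=cfg.kP, kI=cfg.kI, q0=q0)
    elif method == "zhu":
        coeffs = cfg.zhu_length
        yaw = zhu_heading(seq, cfg.k_gyr, cfg.k_mag, cfg.gyro_threshold)
    else:
        coeffs = cfg.hasan_linear
        q0 = _initial_attitude(seq, cfg.init_standstill)
        from .heading import quat_to_euler

        x0 = np.concatenate([quat_to_euler(q0), np.zeros(3)])
        yaw = hasan_ekf(seq, Q=cfg.ekf_Q, R=cfg.ekf_R, x0=x0).yaw

    lengths = [max(0.0, predict(ft, coeffs)) for ft in feats]
    step_yaw = heading_per_step(yaw, events)
    steps = [
        StepVector(length=l, heading=float(yaw_to_heading(y)))
        for l, y in zip(lengths, step_yaw)
    ]
    times = np.array([e.peak_time for e in events])
    return integrate_steps(cfg.start, steps, step_times=times)


def collect_calibration_steps(
    seq: ImuSequence,
    real_length: float | None = None,
    step_length: float | None = None,
    config: PipelineConfig | None = None,
    trim: int = 1,
):
    """Per-step (features, true length) pairs from a walk of known length.

    Runs the detection front end on a calibration walk (typically a
    straight path of measured length), assigns each detected step the
    length ``real_length / n_steps`` (or an explicitly known
    ``step_length``), and drops ``trim`` steps at each end whose windows
    extend into the standstill periods. The result feeds
    :func:`headpdr.steplength.calibrate`.
    """
    if (real_length is None) == (step_length is None):
        raise ValueError("give exactly one of real_length or step_length")
    cfg = config if config is not None else PipelineConfig()
    norm = accel_norm(seq)
    filtered = lowpass(norm, seq.fs, cfg.filter_spec, dt=seq.dt)
    events = detect_steps(filtered, seq.fs, cfg.detector, t=seq.t)
    if len(events) <= 2 * trim:
        raise ValueError("too few detected steps for calibration")
    events = _clamp_windows(step_windows(events, len(seq)), seq.fs, cfg.max_window_factor)
    per_step = step_length if step_length is not None else real_length / len(events)
    kept = events[trim : len(events) - trim] if trim else events
    return [
        (extract_features(filtered[s:e], seq.fs), per_step)
        for s, e in (ev.window for ev in kept)
    ]
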