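"""IMU data model, unit handling and first-order low-pass filtering.

The universal input is an :class:`ImuSequence`: time-stamped tri-axial
accelerometer (m/s^2) and gyroscope (rad/s) streams, with an optional
magnetometer (unit-free field direction), nominally sampled at 20 Hz.
Head-mounted loggers stream over Bluetooth, so timestamps jitter; every
downstream integration and filter therefore uses per-sample dt rather
than assuming a uniform rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRAVITY",
    "ImuSequence",
    "FilterSpec",
    "accel_norm",
    "lowpass",
]

#: Standard gravity magnitude used throughout (m/s^2).
GRAVITY = 9.81


@dataclass
class ImuSequence:
    """Time-stamped tri-axial IMU stream in SI units.

    Parameters
    ----------
    t : (n,) array
        Sample times in seconds, strictly increasing.
    accel : (n, 3) array
        Specific force in the sensor frame, m/s^2.
    gyro : (n, 3) array
        Angular rate in the sensor frame, rad/s.
    mag : (n, 3) array, optional
        Magnetic field direction (unit-free); ``None`` when the stream
        carries no magnetometer.
    nominal_rate : float
        Nominal sampling rate in Hz (20 Hz for the target hardware).
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray | None = None
    nominal_rate: float = 20.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.mag is not None:
            self.mag = np.atleast_2d(np.asarray(self.mag, dtype=float))
        n = len(self.t)
        if n == 0:
            raise ValueError("ImuSequence must contain at least one sample")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"accel/gyro must have shape ({n}, 3); got "
                f"{self.accel.shape} and {self.gyro.shape}"
            )
        if not (np.isfinite(self.accel).all() and np.isfinite(self.gyro).all()):
            raise ValueError("accel and gyro must be finite")
        if self.mag is not None:
            if self.mag.shape != (n, 3):
                raise ValueError(f"mag must have shape ({n}, 3)")
            if np.any(np.linalg.norm(self.mag, axis=1) == 0.0):
                raise ValueError("magnetometer samples must have nonzero norm")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                raise ValueError(f"timestamps must be strictly increasing (row {bad})")
            med = float(np.median(dt))
            if abs(med - 1.0 / self.nominal_rate) > 0.2 / self.nominal_rate:
                raise ValueError(
                    f"median sample interval {med:.4f}s inconsistent with "
                    f"nominal rate {self.nominal_rate} Hz"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def has_mag(self) -> bool:
        return self.mag is not None

    @property
    def dt(self) -> np.ndarray:
        """Per-sample forward time differences, last repeated; (n,) array."""
        if len(self.t) == 1:
            return np.array([1.0 / self.nominal_rate])
        d = np.diff(self.t)
        return np.append(d, d[-1])

    @property
    def fs(self) -> float:
        """Effective sampling rate (Hz) from the median interval."""
        if len(self.t) == 1:
            return self.nominal_rate
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass(frozen=True)
class FilterSpec:
    """First-order low-pass filter specification.

    ``cutoff`` is the -3 dB frequency in Hz; the order is fixed at one.
    The walking-motion default of 2 Hz keeps step oscillations (< ~3 Hz
    cadence) while removing high-frequency sensor noise.
    """

    cutoff: float = 2.0
    order: int = field(default=1)

    def __post_init__(self) -> None:
        if self.order != 1:
            raise ValueError("only first-order filters are supported")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def accel_norm(seq: ImuSequence) -> np.ndarray:
    """Euclidean norm of the accelerometer signal, per sample.

    Returns sqrt(Ax^2 + Ay^2 + Az^2) in m/s^2 for each sample; rotation
    of the sensor frame leaves it unchanged, which is what makes it the
    natural step-detection signal for an arbitrarily-oriented head
    sensor.
    """
    return np.linalg.norm(seq.accel, axis=1)


def lowpass(
    series: np.ndarray,
    fs: float,
    spec: FilterSpec = FilterSpec(),
    dt: np.ndarray | None = None,
) -> np.ndarray:
    """Causal first-order low-pass (exponential smoothing) with DC gain 1.

    Implements ``y[n] = alpha[n] * x[n] + (1 - alpha[n]) * y[n-1]`` with
    ``alpha = dt / (RC + dt)``, ``RC = 1 / (2 pi fc)``, initialised with
    ``y[0] = x[0]``. When ``dt`` is given (per-sample intervals, e.g.
    from jittery Bluetooth timestamps) it supersedes the uniform ``1/fs``
    spacing.

    Raises
    ------
    ValueError
        If the cutoff is at or above the Nyquist frequency.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot filter an empty series")
    if spec.cutoff >= fs / 2.0:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz must be below the Nyquist frequency {fs / 2.0} Hz"
        )
    rc = 1.0 / (2.0 * np.pi * spec.cutoff)
    if dt is None:
        dt_arr = np.full(x.shape[0], 1.0 / fs)
    else:
        dt_arr = np.asarray(dt, dtype=float)
        if dt_arr.shape[0] != x.shape[0]:
            raise ValueError("dt must have the same length as the series")
    alpha = dt_arr / (rc + dt_arr)
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, x.shape[0]):
        y[i] = y[i - 1] + alpha[i] * (x[i] - y[i - 1])
    return y
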