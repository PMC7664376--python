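"""CSV/JSON/YAML readers and writers binding the pipeline together.

IMU CSV dialect: header ``t,ax,ay,az,gx,gy,gz[,mx,my,mz]``,
comma-separated. Accelerations are m/s^2; gyro columns may be logged in
deg/s (declare ``gyro_units="deg"``) and are converted to rad/s at
load. Trajectories are written as ``step,t,x,y`` and step events as
``peak_index,peak_time,win_start,win_end``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signal_core import ImuSequence
from .stepdetect import StepEvent
from .steplength import ModelCoefficients
from .trajectory import Trajectory

__all__ = [
    "read_imu_csv",
    "write_imu_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_steps_csv",
    "write_metrics_json",
    "save_coefficients",
    "load_coefficients",
]

_IMU_COLS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
_MAG_COLS = ["mx", "my", "mz"]


def read_imu_csv(
    path: str | Path, gyro_units: str = "rad", nominal_rate: float = 20.0
) -> ImuSequence:
    """Read an IMU stream; validates monotone time and normalises units."""
    df = pd.read_csv(path)
    missing = [c for c in _IMU_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(f"{path}: non-monotone timestamp at data row {int(bad[0]) + 1}")
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    if gyro_units == "deg":
        gyro = np.deg2rad(gyro)
    elif gyro_units != "rad":
        raise ValueError("gyro_units must be 'rad' or 'deg'")
    mag = None
    if all(c in df.columns for c in _MAG_COLS):
        mag = df[_MAG_COLS].to_numpy(dtype=float)
    return ImuSequence(
        t=t,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=gyro,
        mag=mag,
        nominal_rate=nominal_rate,
    )


def write_imu_csv(path: str | Path, seq: ImuSequence) -> None:
    data = {
        "t": seq.t,
        "ax": seq.accel[:, 0],
        "ay": seq.accel[:, 1],
        "az": seq.accel[:, 2],
        "gx": seq.gyro[:, 0],
        "gy": seq.gyro[:, 1],
        "gz": seq.gyro[:, 2],
    }
    if seq.has_mag:
        data.update({c: seq.mag[:, i] for i, c in enumerate(_MAG_COLS)})
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def write_trajectory_csv(path: str | Path, traj: Trajectory) -> None:
    n = traj.positions.shape[0]
    times = np.full(n, np.nan)
    if traj.step_times is not None and traj.step_times.size:
        times[1:] = traj.step_times
    pd.DataFrame(
        {
            "step": np.arange(n),
            "t": times,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
        }
    ).to_csv(path, index=False, float_format="%.9g")


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    times = df["t"].to_numpy(dtype=float)[1:]
    return Trajectory(
        positions=df[["x", "y"]].to_numpy(dtype=float),
        step_times=None if np.isnan(times).any() else times,
    )


def write_steps_csv(path: str | Path, events: list[StepEvent]) -> None:
    pd.DataFrame(
        {
            "peak_index": [e.peak_index for e in events],
            "peak_time": [e.peak_time for e in events],
            "win_start": [e.window[0] if e.window else -1 for e in events],
            "win_end": [e.window[1] if e.window else -1 for e in events],
        }
    ).to_csv(path, index=False, float_format="%.9g")


def write_metrics_json(path: str | Path, metrics: dict) -> None:
    Path(path).write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")


def save_coefficients(path: str | Path, coeffs: ModelCoefficients) -> None:
    Path(path).write_text(
        yaml.safe_dump({"model_id": coeffs.model_id, "params": coeffs.params})
    )


def load_coefficients(path: str | Path) -> ModelCoefficients:
    data = yaml.safe_load(Path(path).read_text())
    return ModelCoefficients(
        model_id=data["model_id"], params={k: float(v) for k, v in data["params"].items()}
    )
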