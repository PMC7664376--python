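"""Run configuration: a single human-readable YAML file, per-method keys.

Every tunable of the three pipelines lives here so runs are
reproducible from one file plus a seed; CLI flags override file values.
Unknown keys are rejected rather than silently ignored.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import yaml

from .signal_core import FilterSpec
from .stepdetect import DetectorConfig
from .steplength import ModelCoefficients
from .trajectory import PipelineConfig

__all__ = ["load_config", "save_config", "config_hash"]

_KNOWN_KEYS = {
    "filter_cutoff",
    "detector_threshold",
    "detector_min_separation",
    "gyro_units",
    "weinberg",
    "zhu_length",
    "hasan_linear",
    "kP",
    "kI",
    "k_gyr",
    "k_mag",
    "gyro_threshold",
    "ekf_Q_diag",
    "ekf_R_diag",
    "init_standstill",
}


def _coeffs(entry: dict) -> ModelCoefficients:
    return ModelCoefficients(
        model_id=entry["model_id"],
        params={k: float(v) for k, v in entry["params"].items()},
    )


def load_config(path: str | Path) -> tuple[PipelineConfig, str]:
    """Load a pipeline configuration; returns (config, gyro_units)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig()
    if "filter_cutoff" in data:
        cfg.filter_spec = FilterSpec(cutoff=float(data["filter_cutoff"]))
    det = {}
    if "detector_threshold" in data:
        det["threshold"] = float(data["detector_threshold"])
    if "detector_min_separation" in data:
        det["min_separation"] = float(data["detector_min_separation"])
    if det:
        cfg.detector = DetectorConfig(**det)
    for name in ("weinberg", "hasan_linear", "zhu_length"):
        if name in data and data[name] is not None:
            setattr(cfg, name, _coeffs(data[name]))
    for scalar in ("kP", "kI", "k_gyr", "k_mag", "gyro_threshold", "init_standstill"):
        if scalar in data:
            setattr(cfg, scalar, float(data[scalar]))
    if "ekf_Q_diag" in data:
        cfg.ekf_Q = np.diag([float(v) for v in data["ekf_Q_diag"]])
    if "ekf_R_diag" in data:
        cfg.ekf_R = np.diag([float(v) for v in data["ekf_R_diag"]])
    return cfg, str(data.get("gyro_units", "rad"))


def save_config(path: str | Path, cfg: PipelineConfig, gyro_units: str = "rad") -> None:
    data = {
        "filter_cutoff": cfg.filter_spec.cutoff,
        "detector_threshold": cfg.detector.threshold,
        "detector_min_separation": cfg.detector.min_separation,
        "gyro_units": gyro_units,
        "kP": cfg.kP,
        "kI": cfg.kI,
        "k_gyr": cfg.k_gyr,
        "k_mag": cfg.k_mag,
        "gyro_threshold": cfg.gyro_threshold,
        "init_standstill": cfg.init_standstill,
        "weinberg": {"model_id": cfg.weinberg.model_id, "params": cfg.weinberg.params},
        "hasan_linear": {
            "model_id": cfg.hasan_linear.model_id,
            "params": cfg.hasan_linear.params,
        },
    }
    if cfg.zhu_length is not None:
        data["zhu_length"] = {
            "model_id": cfg.zhu_length.model_id,
            "params": cfg.zhu_length.params,
        }
    if cfg.ekf_Q is not None:
        data["ekf_Q_diag"] = [float(v) for v in np.diag(cfg.ekf_Q)]
    if cfg.ekf_R is not None:
        data["ekf_R_diag"] = [float(v) for v in np.diag(cfg.ekf_R)]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(cfg: PipelineConfig) -> str:
    """Short provenance hash of a pipeline configuration."""
    blob = repr(
        (
            cfg.filter_spec,
            cfg.detector,
            cfg.weinberg,
            cfg.zhu_length,
            cfg.hasan_linear,
            cfg.kP,
            cfg.kI,
            cfg.k_gyr,
            cfg.k_mag,
            cfg.gyro_threshold,
            None if cfg.ekf_Q is None else cfg.ekf_Q.tolist(),
            None if cfg.ekf_R is None else cfg.ekf_R.tolist(),
            cfg.init_standstill,
            cfg.start,
        )
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
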