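"""Per-step features, step-length models and coefficient calibration.

Model-based step-length estimators map per-step features of the
accelerometer signal — step frequency f (Hz), acceleration extrema
a_max/a_min (m/s^2), mean absolute acceleration, and within-step
variance v — to a step length in metres:

===========  ====================================================
linear       a*f + b
weinberg     k * (a_max - a_min)^(1/4)
kim          k * (mean|a|)^(1/3)
scarlett     k * (mean|a| - a_min) / (a_max - a_min)
shin         a*f + b*v + c
zhu          a*r_lf*f + r_lv*v + b*(a_max - a_min)^(1/4)
===========  ====================================================

where the zhu hybrid weights r_lf and r_lv are the Pearson correlations
of step length with frequency and with variance over a calibration set.
Coefficients do not transfer well between individuals, so
:func:`calibrate` fits them per subject from steps of known length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "MODEL_IDS",
    "StepFeatures",
    "ModelCoefficients",
    "extract_features",
    "linear_model",
    "weinberg_model",
    "kim_model",
    "scarlett_model",
    "shin_model",
    "zhu_hybrid_model",
    "pearson_r",
    "predict",
    "calibrate",
]

MODEL_IDS = ("linear", "weinberg", "kim", "scarlett", "shin", "zhu")

#: Weinberg gain shipped for simulator demos; per-subject calibration
#: from a straight walk of known length is always preferred.
DEFAULT_WEINBERG_K = 0.48


@dataclass(frozen=True)
class StepFeatures:
    """Scalar features of one step's acceleration segment."""

    f: float  # step frequency, Hz (1 / duration)
    a_max: float  # maximum acceleration in the step, m/s^2
    a_min: float  # minimum acceleration in the step, m/s^2
    mean_abs: float  # mean absolute acceleration, m/s^2
    var: float  # population variance of the acceleration, (m/s^2)^2
    duration: float  # step duration, s

    def __post_init__(self) -> None:
        if self.a_max < self.a_min:
            raise ValueError("a_max must be >= a_min")
        if self.var < 0 or self.duration <= 0:
            raise ValueError("invalid step features")


@dataclass
class ModelCoefficients:
    """A step-length model identifier with its fitted parameters."""

    model_id: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}; choose from {MODEL_IDS}")
        if self.model_id in ("weinberg", "kim", "scarlett") and self.params.get("k", 1.0) <= 0:
            raise ValueError("k must be positive")
        for r in ("r_lf", "r_lv"):
            if r in self.params and not -1.0 <= self.params[r] <= 1.0:
                raise ValueError(f"{r} must lie in [-1, 1]")


def extract_features(segment: np.ndarray, fs: float) -> StepFeatures:
    """Features of one step from its acceleration segment.

    Uses the population variance (divide by N) and defines the step
    frequency as ``fs / N`` where N is the segment length.
    """
    a = np.asarray(segment, dtype=float)
    n = a.shape[0]
    if n < 2:
        raise ValueError("degenerate step: segment must contain at least 2 samples")
    return StepFeatures(
        f=fs / n,
        a_max=float(a.max()),
        a_min=float(a.min()),
        mean_abs=float(np.mean(np.abs(a))),
        var=float(np.var(a)),
        duration=n / fs,
    )


def linear_model(feat: StepFeatures, coeffs: ModelCoefficients) -> float:
    p = coeffs.params
    return p["a"] * feat.f + p["b"]


def weinberg_model(feat: StepFeatures, coeffs: ModelCoefficients) -> float:
    diff = feat.a_max - feat.a_min
    if diff == 0.0:
        log.warning("weinberg_model: a_max == a_min, returning 0")
        return 0.0
    return coeffs.params["k"] * diff**0.25


def kim_model(feat: StepFeatures, coeffs: ModelCoefficients) -> float:
    return coeffs.params["k"] * feat.mean_abs ** (1.0 / 3.0)


def scarlett_model(feat: StepFeatures, coeffs: ModelCoefficients) -> float:
    diff = feat.a_max - feat.a_min
    if diff == 0.0:
        raise ZeroDivisionError("scarlett_model: a_max == a_min")
    return coeffs.params["k"] * (feat.mean_abs - feat.a_min) / diff


def shin_model(feat: StepFeatures, coeffs: ModelCoefficients) -> float:
    p = coeffs.params
    return p["a"] * feat.f + p["b"] * feat.var + p["c"]


def zhu_hybrid_model(feat: StepFeatures, coeffs: ModelCoefficients) -> float:
    p = coeffs.params
    diff = feat.a_max - feat.a_min
    return p["a"] * p["r_lf"] * feat.f + p["r_lv"] * feat.var + p["b"] * diff**0.25


_MODEL_FUNCS = {
    "linear": linear_model,
    "weinberg": weinberg_model,
    "kim": kim_model,
    "scarlett": scarlett_model,
    "shin": shin_model,
    "zhu": zhu_hybrid_model,
}


def predict(feat: StepFeatures, coeffs: ModelCoefficients) -> float:
    """Step length (m) from features under the given model."""
    return _MODEL_FUNCS[coeffs.model_id](feat, coeffs)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.shape[0] < 2:
        raise ValueError("pearson_r needs two equal-length 1-d series of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0.0:
        raise ValueError("pearson_r undefined: a series has zero variance")
    return float(np.clip(np.dot(xc, yc) / denom, -1.0, 1.0))


def _design_matrix(model_id: str, feats: list[StepFeatures]) -> tuple[np.ndarray, list[str]]:
    f = np.array([ft.f for ft in feats])
    v = np.array([ft.var for ft in feats])
    diff = np.array([ft.a_max - ft.a_min for ft in feats])
    mean_abs = np.array([ft.mean_abs for ft in feats])
    a_min = np.array([ft.a_min for ft in feats])
    if model_id == "linear":
        return np.column_stack([f, np.ones_like(f)]), ["a", "b"]
    if model_id == "weinberg":
        return diff[:, None] ** 0.25, ["k"]
    if model_id == "kim":
        return mean_abs[:, None] ** (1.0 / 3.0), ["k"]
    if model_id == "scarlett":
        return ((mean_abs - a_min) / diff)[:, None], ["k"]
    if model_id == "shin":
        return np.column_stack([f, v, np.ones_like(f)]), ["a", "b", "c"]
    raise ValueError(f"unknown model {model_id!r}")


def calibrate(
    model_id: str, steps: list[tuple[StepFeatures, float]]
) -> ModelCoefficients:
    """Least-squares fit of a model's coefficients from known step lengths.

    ``steps`` pairs each step's features with its true length in metres
    (e.g. path length / step count over a straight walk). Every model is
    linear in its coefficients, so ordinary least squares applies; for
    the zhu hybrid, the correlation weights r_lf and r_lv are computed
    first from the calibration set, then (a, b) are fit.

    Raises
    ------
    ValueError
        On fewer observations than free parameters or a rank-deficient
        design (e.g. all steps identical for a two-parameter model).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    feats = [ft for ft, _ in steps]
    lengths = np.array([l for _, l in steps], dtype=float)

    if model_id == "zhu":
        f = np.array([ft.f for ft in feats])
        v = np.array([ft.var for ft in feats])
        diff = np.array([ft.a_max - ft.a_min for ft in feats])
        r_lf = pearson_r(lengths, f)
        r_lv = pearson_r(lengths, v)
        # remaining free coefficients: l - r_lv*v = a*(r_lf*f) + b*diff^(1/4)
        design = np.column_stack([r_lf * f, diff**0.25])
        target = lengths - r_lv * v
        names = ["a", "b"]
        extra = {"r_lf": r_lf, "r_lv": r_lv}
    else:
        design, names = _design_matrix(model_id, feats)
        target = lengths
        extra = {}

    if lengths.shape[0] < design.shape[1]:
        raise ValueError(
            f"calibration needs at least {design.shape[1]} steps, got {lengths.shape[0]}"
        )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("calibration design is rank-deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol, *_ = np.linalg.lstsq(design, target, rcond=None)
    params = dict(zip(names, (float(s) for s in sol)))
    params.update(extra)
    return ModelCoefficients(model_id=model_id, params=params)
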