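"""Peak-detection step detection on the filtered accelerometer norm.

During level walking the low-pass-filtered accelerometer norm oscillates
about gravity, with one maximum per step (heel strike); local maxima
that cross a minimum threshold are detected as steps, and a minimum
peak-to-peak separation suppresses double peaks within one gait cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_core import GRAVITY

__all__ = ["StepEvent", "DetectorConfig", "detect_steps", "step_windows"]


@dataclass
class StepEvent:
    """A detected step: the peak sample and its half-open window.

    ``window`` is ``(start, end)`` with ``start <= peak_index < end``;
    windows of consecutive steps tile the walking interval without
    overlap so per-step features can be extracted from disjoint
    segments.
    """

    peak_index: int
    peak_time: float
    window: tuple[int, int] | None = None


@dataclass(frozen=True)
class DetectorConfig:
    """Peak-detector tuning.

    threshold : minimum filtered-norm peak height (m/s^2). The filtered
        norm oscillates about gravity while walking, so the default is
        gravity + 0.5.
    min_separation : minimum peak-to-peak spacing in seconds; 0.3 s
        corresponds to a maximum cadence of ~3.3 steps/s.
    """

    threshold: float = GRAVITY + 0.5
    min_separation: float = 0.3

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_separation < 0:
            raise ValueError("min_separation must be non-negative")


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices i with x[i-1] < x[i] >= x[i+1] (first sample of a plateau)."""
    n = x.shape[0]
    if n < 3:
        return np.empty(0, dtype=int)
    rising = x[1:-1] > x[:-2]
    not_falling_after = x[1:-1] >= x[2:]
    return np.flatnonzero(rising & not_falling_after) + 1


def detect_steps(
    filtered: np.ndarray,
    fs: float,
    cfg: DetectorConfig = DetectorConfig(),
    t: np.ndarray | None = None,
) -> list[StepEvent]:
    """Detect steps as threshold-crossing peaks of the filtered norm.

    All local maxima above ``cfg.threshold`` are candidates; candidates
    are accepted best-first (highest peak first, earlier index breaking
    ties) and any candidate within ``min_separation`` seconds of an
    already-accepted peak is suppressed. Returned events are sorted by
    time. An empty result is valid (e.g. standing still).

    Parameters
    ----------
    filtered : low-pass-filtered accelerometer-norm series.
    fs : sampling rate in Hz.
    cfg : detector configuration.
    t : optional per-sample times; defaults to ``arange(n)/fs``.
    """
    x = np.asarray(filtered, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    times = np.arange(x.shape[0]) / fs if t is None else np.asarray(t, dtype=float)
    candidates = [i for i in _local_maxima(x) if x[i] > cfg.threshold]
    # best-first greedy suppression: higher peaks win; earlier index on ties
    order = sorted(candidates, key=lambda i: (-x[i], i))
    accepted: list[int] = []
    for i in order:
        if all(abs(times[i] - times[j]) >= cfg.min_separation for j in accepted):
            accepted.append(i)
    accepted.sort()
    return [StepEvent(peak_index=int(i), peak_time=float(times[i])) for i in accepted]


def step_windows(events: list[StepEvent], n_samples: int) -> list[StepEvent]:
    """Assign per-step windows with boundaries midway between peaks.

    The first window starts at sample 0 and the last ends at
    ``n_samples``; interior boundaries sit at the midpoint between
    adjacent peaks, so the windows tile ``[0, n_samples)`` without
    overlap. Returns new events; an empty input yields an empty list.
    """
    if not events:
        return []
    peaks = [e.peak_index for e in events]
    if any(b <= a for a, b in zip(peaks, peaks[1:])):
        raise ValueError("events must be sorted with strictly increasing peaks")
    if peaks[-1] >= n_samples:
        raise ValueError("peak index beyond n_samples")
    bounds = [0]
    for a, b in zip(peaks, peaks[1:]):
        bounds.append((a + b + 1) // 2)
    bounds.append(n_samples)
    return [
        StepEvent(peak_index=e.peak_index, peak_time=e.peak_time, window=(s, t))
        for e, s, t in zip(events, bounds[:-1], bounds[1:])
    ]
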