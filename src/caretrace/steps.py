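"""Accelerometer step detection and the moving/stationary state.

Steps are detected on the Euclidean norm of the tri-axial acceleration
(gravity included, so the resting magnitude sits near 9.81 m/s²) with a
two-state threshold machine: the detector arms when the magnitude exceeds
the upper threshold and emits one step when it next falls below the lower
threshold.  A position-update gate reports "moving" while a step has been
seen within a timeout window (3 s by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DetectorConfig",
    "StepEvent",
    "force_magnitude",
    "detect_steps",
    "motion_state",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds in m/s² and the motion timeout in seconds."""

    upper: float = 10.3
    lower: float = 9.1
    timeout: float = 3.0
    smooth_window: Optional[int] = None  # odd sample count; None = no smoothing

    def __post_init__(self) -> None:
        if not (self.upper > self.lower > 0):
            raise ValueError("need upper > lower > 0")
        if self.timeout <= 0:
            raise ValueError("timeout must be positive")


@dataclass(frozen=True)
class StepEvent:
    t: float  # time of the lower-threshold crossing completing the step


def force_magnitude(x, y, z):
    """Euclidean norm of the acceleration vector, scalar or elementwise."""
    x, y, z = np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise ValueError("non-finite acceleration component")
    out = np.sqrt(x * x + y * y + z * z)
    return float(out) if out.ndim == 0 else out


def detect_steps(
    t: Sequence[float],
    magnitude: Sequence[float],
    config: DetectorConfig | None = None,
) -> list[StepEvent]:
    """Run the dual-threshold state machine over a magnitude series.

    Strict inequalities at both thresholds: a sample exactly at a threshold
    neither arms nor completes a step.  The step timestamp is the sample at
    which the magnitude first drops below the lower threshold.
    """
    config = config or DetectorConfig()
    t = np.asarray(t, float)
    mag = np.asarray(magnitude, float)
    if t.shape != mag.shape:
        raise ValueError("time and magnitude lengths differ")
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if config.smooth_window and config.smooth_window > 1:
        w = config.smooth_window
        kernel = np.ones(w) / w
        mag = np.convolve(mag, kernel, mode="same")

    events: list[StepEvent] = []
    armed = False
    for ti, mi in zip(t, mag):
        if not armed:
            if mi > config.upper:
                armed = True
        elif mi < config.lower:
            events.append(StepEvent(t=float(ti)))
            armed = False
    return events


def motion_state(
    steps: Sequence[StepEvent], t: float, config: DetectorConfig | None = None
) -> str:
    """'moving' iff a step occurred in the half-open window (t − timeout, t]."""
    config = config or DetectorConfig()
    for ev in reversed(steps):
        if ev.t <= t:
            return "moving" if t - ev.t < config.timeout else "stationary"
    return "stationary"
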