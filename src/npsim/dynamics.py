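"""Shared numerical substrate: exponential fixed-point updates and adaptive thresholds.

Every activation variable in the model relaxes toward a (possibly moving)
fixed point with an asymmetric per-step gain: a *rise* rate ``rho`` applies
when the target lies above the current value (actively driven growth) and a
*decay* rate ``delta`` when it lies below (passive decay).  One update step
corresponds to 1 ms of behavioural time; the clock constants below convert
display events into step indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ActivationVar",
    "ClockConfig",
    "ThresholdVar",
    "step_exponential",
    "step_threshold",
    "InvalidStateError",
    "ConfigurationError",
]


class InvalidStateError(RuntimeError):
    """A dynamical variable left the finite domain."""


class ConfigurationError(ValueError):
    """A structural/parameter precondition was violated."""


@dataclass
class ActivationVar:
    """A single activation with asymmetric rise/decay rates.

    Parameters
    ----------
    value : float
        Current (dimensionless) activation.
    rise_rate : float
        Per-step gain applied when the drive target exceeds ``value``;
        must lie in (0, 1).
    decay_rate : float
        Per-step gain applied when the drive target is below ``value``;
        must lie in (0, 1).
    """

    value: float
    rise_rate: float
    decay_rate: float

    def __post_init__(self) -> None:
        if not (0.0 < self.rise_rate < 1.0) or not (0.0 < self.decay_rate < 1.0):
            raise ConfigurationError(
                f"rates must lie in (0, 1); got rise={self.rise_rate}, decay={self.decay_rate}"
            )
        if not math.isfinite(self.value):
            raise InvalidStateError(f"non-finite activation {self.value!r}")

    def step(self, target: float) -> float:
        self.value = step_exponential(self.value, target, self.rise_rate, self.decay_rate)
        return self.value


@dataclass(frozen=True)
class ClockConfig:
    """Timing constants mapping display events onto update steps (1 step = 1 ms).

    ``t_recognition`` is the lag between display onset and perceptual input
    arriving at the feature layers, ``t_afterimage`` how long input persists
    after offset, and ``t_motor`` the fixed motor time added between the
    decision step and the recorded response.
    """

    t_recognition: int = 50
    t_afterimage: int = 30
    t_motor: int = 80
    dt: int = 1

    def __post_init__(self) -> None:
        for name in ("t_recognition", "t_afterimage", "t_motor", "dt"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a nonnegative integer, got {v!r}")


def step_exponential(x: float, target: float, rho: float, delta: float) -> float:
    """One exponential fixed-point update ``x + tau * (target - x)``.

    ``tau`` is ``rho`` when the target lies above ``x`` (rise) and ``delta``
    otherwise (decay).  The fixed point of the iterated map is ``target``.
    """
    if not (0.0 < rho < 1.0) or not (0.0 < delta < 1.0):
        raise ConfigurationError(f"rates must lie in (0, 1); got rho={rho}, delta={delta}")
    if not (math.isfinite(x) and math.isfinite(target)):
        raise InvalidStateError(f"non-finite input to step_exponential: x={x}, target={target}")
    tau = rho if target > x else delta
    return x + tau * (target - x)


@dataclass
class ThresholdVar:
    """Adaptive threshold tracking a scaled sum of supra-baseline activations.

    One step advances ``theta`` by ``tau * (nu * sum_j(x_j - baseline)
    - (theta - baseline))``; the fixed point for constant activations is
    ``baseline + nu * sum_j(x_j - baseline)``.  The semantic layer uses the
    activation baseline as its virtual zero; the action layer uses 0.
    """

    value: float
    time_scale: float
    scale: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.time_scale <= 0.0 or self.scale <= 0.0:
            raise ConfigurationError(
                f"time_scale and scale must be positive; got {self.time_scale}, {self.scale}"
            )
        if not math.isfinite(self.value):
            raise InvalidStateError(f"non-finite threshold {self.value!r}")

    def fixed_point(self, activations: Sequence[float]) -> float:
        arr = np.asarray(activations, dtype=float)
        return self.baseline + self.scale * float(np.sum(arr - self.baseline))

    def step(self, activations: Sequence[float]) -> float:
        self.value = step_threshold(self, activations)
        return self.value


def step_threshold(theta: ThresholdVar, activations: Sequence[float]) -> float:
    """One step of the adaptive-threshold dynamics; returns the new level."""
    arr = np.asarray(activations, dtype=float)
    if arr.size == 0:
        raise ConfigurationError("threshold requires at least one activation")
    drive = theta.scale * float(np.sum(arr - theta.baseline))
    return theta.value + theta.time_scale * (drive - (theta.value - theta.baseline))
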