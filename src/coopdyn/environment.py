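"""Environment schedules: the map from a time step to the environmental
resource availability ``R0_t``.

Two kinds are supported: a constant baseline, and a sinusoid

    R0_t = R00 + A * sin(2 * pi * t / P)

with amplitude ``A`` and period ``P`` steps.  The amplitude is required to
stay strictly below the baseline so resources remain positive at every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidScheduleError

__all__ = ["EnvironmentSchedule", "constant", "sinusoidal", "resource_at"]


@dataclass(frozen=True)
class EnvironmentSchedule:
    """A forcing schedule for the environmental resource baseline.

    Attributes
    ----------
    kind : {"constant", "sinusoidal"}
    R00 : float
        Baseline resource availability (> 0).
    A : float
        Amplitude; 0 for constant schedules, else ``0 <= A < R00``.
    P : int
        Period in steps (>= 2); ignored for constant schedules.
    """

    kind: str
    R00: float
    A: float = 0.0
    P: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoidal"):
            raise InvalidScheduleError(f"unknown schedule kind {self.kind!r}")
        if self.R00 <= 0:
            raise InvalidScheduleError("R00 must be positive")
        if self.kind == "sinusoidal":
            if not 0.0 <= self.A < self.R00:
                raise InvalidScheduleError(
                    "amplitude must satisfy 0 <= A < R00 so resources stay positive"
                )
            if self.P < 2:
                raise InvalidScheduleError("period P must be >= 2 steps")


def constant(R00: float) -> EnvironmentSchedule:
    """A constant environment at baseline ``R00``."""
    return EnvironmentSchedule(kind="constant", R00=R00)


def sinusoidal(R00: float, A: float, P: int) -> EnvironmentSchedule:
    """A sinusoidal environment of amplitude ``A`` and period ``P`` steps."""
    return EnvironmentSchedule(kind="sinusoidal", R00=R00, A=A, P=P)


def resource_at(schedule: EnvironmentSchedule, t):
    """Environmental resource availability ``R0_t`` at integer step ``t``.

    The sinusoid is evaluated at ``t mod P`` so that integer-period
    periodicity holds exactly in floating point.
    """
    t = np.asarray(t)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if schedule.kind == "constant":
        out = np.broadcast_to(np.float64(schedule.R00), t.shape).copy()
        return out if out.ndim else float(schedule.R00)
    phase = np.asarray(t % schedule.P, dtype=float)
    out = schedule.R00 + schedule.A * np.sin(2.0 * np.pi * phase / schedule.P)
    return out if out.ndim else float(out)
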