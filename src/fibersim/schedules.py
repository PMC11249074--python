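"""Time-dependent parameter overlays.

The constant-parameter model cannot produce the turgor/osmotic pressure
peaks observed in developing cotton fibers, so the dynamic experiments make
one (or more) of the three most influential parameters — wall extensibility
``phi``, plasmodesmal permeability ``mu``, solute source ``alpha`` — a
function of time.  A :class:`ParameterSchedule` replaces a single parameter
of a base :class:`~fibersim.model_core.ModelParameters` with a simple
temporal shape:

``constant``
    the base value at all times (identity overlay);
``linear_decay``
    base value at t = 0, decreasing linearly to zero at ``t_end_decay`` and
    zero afterwards (growth arrest by wall stiffening);
``closure_window``
    zero inside the closed interval [t_start, t_start + duration], base
    value outside (transient plasmodesmata closure);
``pulse``
    ``high_value`` inside the closed window, base value outside (transient
    boost of the solute source).

Times are seconds; window boundaries belong to the window (closed on both
ends) — the simulator restarts integration at every breakpoint, so boundary
membership only affects a measure-zero set, but a fixed convention keeps
outputs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .model_core import ModelParameters

__all__ = ["ParameterSchedule", "evaluate_schedule", "apply_schedules", "breakpoints"]

_SCHEDULABLE = ("phi", "mu", "alpha")
_SHAPES = ("constant", "linear_decay", "closure_window", "pulse")


@dataclass(frozen=True)
class ParameterSchedule:
    """Temporal overlay for one model parameter.

    Parameters
    ----------
    parameter_name : {"phi", "mu", "alpha"}
        Which parameter the overlay replaces.
    shape : {"constant", "linear_decay", "closure_window", "pulse"}
    t_start : float
        Window/pulse start, s (ignored by constant and linear_decay).
    duration : float
        Window/pulse length, s.
    t_end_decay : float
        Time at which a linear decay reaches zero, s.
    high_value : float
        Plateau value of a pulse, in the parameter's own units.
    """

    parameter_name: str
    shape: str
    t_start: float = 0.0
    duration: float = 0.0
    t_end_decay: float = 0.0
    high_value: float = 0.0

    def __post_init__(self) -> None:
        if self.parameter_name not in _SCHEDULABLE:
            raise ValueError(
                f"schedulable parameters are {_SCHEDULABLE}, got {self.parameter_name!r}"
            )
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown schedule shape {self.shape!r}")
        if self.t_start < 0 or self.duration < 0:
            raise ValueError("schedule times must be non-negative")
        if self.shape == "linear_decay" and not self.t_end_decay > 0:
            raise ValueError("linear_decay requires t_end_decay > 0")
        if self.shape == "pulse" and self.high_value < 0:
            raise ValueError("pulse high_value must be >= 0")

    def value_at(self, base_value: float, t: float) -> float:
        """Scheduled value of the parameter at time ``t`` (s)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        if self.shape == "constant":
            return base_value
        if self.shape == "linear_decay":
            return base_value * max(0.0, 1.0 - t / self.t_end_decay)
        in_window = self.t_start <= t <= self.t_start + self.duration
        if self.shape == "closure_window":
            return 0.0 if in_window else base_value
        # pulse
        return self.high_value if in_window else base_value

    def breakpoints(self) -> List[float]:
        """Times at which the overlay is non-smooth (integration restarts)."""
        if self.shape == "constant":
            return []
        if self.shape == "linear_decay":
            return [self.t_end_decay]
        return [self.t_start, self.t_start + self.duration]


def evaluate_schedule(
    schedule: ParameterSchedule, base: ModelParameters, t: float
) -> ModelParameters:
    """Return ``base`` with the scheduled parameter replaced by its value at ``t``."""
    base_value = getattr(base, schedule.parameter_name)
    return base.replace(**{schedule.parameter_name: schedule.value_at(base_value, t)})


def apply_schedules(
    schedules: Sequence[ParameterSchedule], base: ModelParameters, t: float
) -> ModelParameters:
    """Apply every schedule in turn (each overlays its own parameter)."""
    params = base
    for schedule in schedules:
        params = evaluate_schedule(schedule, base=params, t=t)
    return params


def breakpoints(
    schedules: Sequence[ParameterSchedule], t_max: Optional[float] = None
) -> List[float]:
    """Sorted unique breakpoint times of all schedules, clipped to (0, t_max)."""
    times = set()
    for schedule in schedules:
        times.update(schedule.breakpoints())
    if t_max is not None:
        times = {t for t in times if 0.0 < t < t_max}
    return sorted(times)
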