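"""Forward integration of the two-variable fiber model.

The state integrated is ``(ln V, pi_fiber)``: fiber volume grows by many
orders of magnitude over a 3,000 h horizon and log-volume keeps the relative
error uniform.  The right-hand side is only piecewise smooth (positive parts
in the growth law and solute advection, window-shaped parameter schedules),
so integration is split at every schedule breakpoint and an adaptive
implicit-capable stepper (LSODA) is used within each smooth segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import model_core
from .model_core import FiberState, ModelParameters
from .schedules import ParameterSchedule, apply_schedules, breakpoints

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "simulate",
    "detect_steady_state",
    "extract_extrema",
    "HOUR",
]

HOUR = 3600.0  # s


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed for one forward run (SI units).

    ``pi0 = None`` means "start at the seed osmotic pressure", the standard
    initial condition of the model.
    """

    params: ModelParameters
    schedules: Tuple[ParameterSchedule, ...] = ()
    V0: float = 1.88e-13
    pi0: Optional[float] = None
    t_max: float = 500.0 * HOUR
    output_grid: int = 2001
    rel_tol: float = 1e-8
    abs_tol_logV: float = 1e-10
    abs_tol_pi: float = 1e-2

    def __post_init__(self) -> None:
        if not self.V0 > 0:
            raise ValueError("V0 must be > 0")
        if not self.t_max > 0:
            raise ValueError("t_max must be > 0")
        if self.output_grid < 2:
            raise ValueError("output_grid must be >= 2")
        if not (self.rel_tol > 0 and self.abs_tol_logV > 0 and self.abs_tol_pi > 0):
            raise ValueError("tolerances must be > 0")

    @property
    def initial_pi(self) -> float:
        return self.params.pi_seed if self.pi0 is None else self.pi0

    def replace(self, **changes) -> "SimulationConfig":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass
class Trajectory:
    """Dense output of a simulation on a uniform time grid (SI units).

    ``log_V`` is carried alongside ``V`` so downstream volume ratios can be
    formed without overflowing even after extreme growth.
    """

    t: np.ndarray
    V: np.ndarray
    log_V: np.ndarray
    pi_fiber: np.ndarray
    dP: np.ndarray
    P_fiber: np.ndarray
    F_m: np.ndarray
    F_p: np.ndarray
    rgr: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)

    def to_dataframe(self) -> pd.DataFrame:
        """Human-unit view: hours, mm^3, MPa, mm^3/h."""
        M3_TO_MM3 = 1e9
        return pd.DataFrame(
            {
                "t_h": self.t / HOUR,
                "V_mm3": self.V * M3_TO_MM3,
                "pi_fiber_MPa": self.pi_fiber / 1e6,
                "P_fiber_MPa": self.P_fiber / 1e6,
                "dP_MPa": self.dP / 1e6,
                "F_m_mm3_per_h": self.F_m * M3_TO_MM3 * HOUR,
                "F_p_mm3_per_h": self.F_p * M3_TO_MM3 * HOUR,
                "rgr_per_h": self.rgr * HOUR,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def variable(self, name: str) -> np.ndarray:
        if name not in ("pi_fiber", "P_fiber", "V", "rgr", "log_V"):
            raise ValueError(f"unknown trajectory variable {name!r}")
        return getattr(self, name)


def _segment_rhs(base: ModelParameters, schedules: Sequence[ParameterSchedule], t_mid: float):
    """RHS valid on one smooth segment.

    Window-shaped overlays (closure, pulse) are frozen at the segment
    midpoint so the solver never straddles a discontinuity; linear decays
    stay time-continuous.
    """
    const_params = base
    decays: List[ParameterSchedule] = []
    for schedule in schedules:
        if schedule.shape == "linear_decay":
            decays.append(schedule)
        else:
            const_params = const_params.replace(
                **{
                    schedule.parameter_name: schedule.value_at(
                        getattr(const_params, schedule.parameter_name), t_mid
                    )
                }
            )

    def f(t: float, y: np.ndarray) -> List[float]:
        params = const_params
        for schedule in decays:
            params = params.replace(
                **{
                    schedule.parameter_name: schedule.value_at(
                        getattr(params, schedule.parameter_name), t
                    )
                }
            )
        log_V, pi = y
        state = FiberState(V=math.exp(log_V), pi_fiber=max(pi, 0.0))
        dV_dt, dpi_dt = model_core.rhs(params, state)
        return [dV_dt / state.V, dpi_dt]

    return f


def simulate(config: SimulationConfig) -> Trajectory:
    """Integrate the model over ``[0, t_max]`` and return a dense trajectory.

    Integration restarts at every schedule breakpoint; within each segment
    the solution is obtained with LSODA under ``(rel_tol, abs_tol)`` control
    and sampled on the uniform output grid via dense output.
    """
    t_grid = np.linspace(0.0, config.t_max, config.output_grid)
    edges = [0.0] + breakpoints(config.schedules, config.t_max) + [config.t_max]

    log_V = np.empty_like(t_grid)
    pi = np.empty_like(t_grid)
    y = np.array([math.log(config.V0), config.initial_pi])
    log_V[0], pi[0] = y

    for t0, t1 in zip(edges[:-1], edges[1:]):
        f = _segment_rhs(config.params, config.schedules, 0.5 * (t0 + t1))
        sol = solve_ivp(
            f,
            (t0, t1),
            y,
            method="LSODA",
            dense_output=True,
            rtol=config.rel_tol,
            atol=[config.abs_tol_logV, config.abs_tol_pi],
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t = {sol.t[-1] / HOUR:.3f} h: {sol.message}"
            )
        if not np.all(np.isfinite(sol.y)):
            raise RuntimeError(f"non-finite state in segment [{t0}, {t1}] s")
        mask = (t_grid > t0) & (t_grid <= t1)
        if mask.any():
            vals = sol.sol(t_grid[mask])
            log_V[mask] = vals[0]
            pi[mask] = np.maximum(vals[1], 0.0)
        y = sol.y[:, -1]

    V = np.exp(log_V)
    n = t_grid.size
    dP = np.empty(n)
    F_m = np.empty(n)
    F_p = np.empty(n)
    rgr = np.empty(n)
    for i in range(n):
        params_t = apply_schedules(config.schedules, config.params, t_grid[i])
        state = FiberState(V=V[i], pi_fiber=pi[i])
        d = model_core.derived_quantities(params_t, state)
        dP[i], F_m[i], F_p[i], rgr[i] = d.dP, d.F_m, d.F_p, d.rgr

    return Trajectory(
        t=t_grid,
        V=V,
        log_V=log_V,
        pi_fiber=pi,
        dP=dP,
        P_fiber=dP + config.params.P_seed,
        F_m=F_m,
        F_p=F_p,
        rgr=rgr,
        config=config,
    )


def detect_steady_state(traj: Trajectory, tol: float = 0.01) -> Optional[float]:
    """Earliest time after which both pressures are relatively stationary.

    A pressure ``p`` is stationary at a sample when
    ``|dp/dt| * t_max / p < tol`` — i.e. at the current rate it would change
    by less than a fraction ``tol`` of itself over the whole horizon.
    Returns ``None`` if the condition never holds through the end.
    """
    t = traj.t
    t_max = t[-1]
    ok = np.ones_like(t, dtype=bool)
    for p in (traj.pi_fiber, traj.P_fiber):
        rate = np.gradient(p, t)
        scale = np.maximum(np.abs(p), 1e-300)
        ok &= np.abs(rate) * t_max / scale < tol
    # earliest index from which the condition holds for every later sample
    holds_to_end = np.flip(np.logical_and.accumulate(np.flip(ok)))
    idx = np.nonzero(holds_to_end)[0]
    if idx.size == 0:
        return None
    return float(t[idx[0]])


def extract_extrema(
    traj: Trajectory,
    variable: str,
    transient_fraction: float = 0.05,
    rel_guard: float = 1e-9,
) -> List[Tuple[float, float, str]]:
    """Interior local extrema of a trajectory variable.

    The first ``transient_fraction`` of the horizon is discarded (only the
    first few hours depend on the initial condition) and a point counts as an
    extremum only if it exceeds both neighbours by more than ``rel_guard``
    times the variable's scale, which suppresses solver ripple.  An empty
    list means the variable is monotonic on the retained window.
    """
    y = traj.variable(variable)
    t = traj.t
    start = int(np.searchsorted(t, transient_fraction * t[-1]))
    y = y[start:]
    t = t[start:]
    if y.size < 3:
        return []
    guard = rel_guard * float(np.max(np.abs(y)))
    out: List[Tuple[float, float, str]] = []
    for i in range(1, y.size - 1):
        if y[i] > y[i - 1] + guard and y[i] > y[i + 1] + guard:
            out.append((float(t[i]), float(y[i]), "max"))
        elif y[i] < y[i - 1] - guard and y[i] < y[i + 1] - guard:
            out.append((float(t[i]), float(y[i]), "min"))
    return out
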