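"""Pressure-behavior classification and dynamic-parameter scenarios.

With constant parameters drawn from the biological ranges the model only
produces monotonic osmotic and turgor pressure histories; the transient
pressure peaks observed in developing fibers require time-dependent
parameters.  This module provides

* an analytic screen (:func:`peak_condition`) for the necessary condition
  under which constant parameters could produce a pressure peak — evaluated
  verbatim in its published product form (see
  :func:`peak_condition_diagnostics` for the caveat);
* a numerical classifier (:func:`classify`) labelling each pressure
  trajectory as monotonic, single peak, single trough, or otherwise;
* the canonical dynamic-parameter scenarios (extensibility decay,
  transient plasmodesmata closure, solute-source pulse, and combinations),
  and the closure-timing sweep mapping final fiber size against the start
  and duration of plasmodesmata closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import ModelParameters
from .schedules import ParameterSchedule
from .sensitivity import default_table, reference_parameters
from .simulator import (
    HOUR,
    SimulationConfig,
    Trajectory,
    extract_extrema,
    simulate,
)

__all__ = [
    "BehaviorLabel",
    "ScenarioResult",
    "ClosureSweepResult",
    "SCENARIOS",
    "peak_condition",
    "peak_condition_diagnostics",
    "classify",
    "run_scenario",
    "closure_sweep",
]

SCENARIOS = ("reference", "phi_decay", "mu_closure", "combined", "alpha_pulse")

# defaults shared by the dynamic scenarios (seconds)
PHI_DECAY_END = 500.0 * HOUR
CLOSURE_START = 200.0 * HOUR
CLOSURE_DURATION = 50.0 * HOUR
ALPHA_PULSE_START = 200.0 * HOUR
ALPHA_PULSE_DURATION = 50.0 * HOUR


@dataclass(frozen=True)
class BehaviorLabel:
    """Qualitative label of one pressure variable's trajectory."""

    variable: str
    label: str
    extremum_time: Optional[float] = None


@dataclass
class ScenarioResult:
    scenario: str
    trajectory: Trajectory
    labels: Dict[str, BehaviorLabel]
    extrema: Dict[str, List[Tuple[float, float, str]]]
    final_volume_ratio: float


@dataclass
class ClosureSweepResult:
    """Normalized final volumes over a (closure start, closure duration) grid.

    ``normalized[i, j]`` is ``V(t_max)`` for closure starting at
    ``t0_grid[i]`` with duration ``tdist_grid[j]``, divided by the anchor
    cell's final volume.  ``log_ratio`` carries the same information in log
    space (safe against overflow).  ``clipped`` flags windows extending
    beyond the horizon.
    """

    t0_grid: np.ndarray
    tdist_grid: np.ndarray
    log_ratio: np.ndarray
    clipped: np.ndarray
    anchor: Tuple[float, float]
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.normalized = np.exp(self.log_ratio)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, t0 in enumerate(self.t0_grid):
            for j, td in enumerate(self.tdist_grid):
                rows.append(
                    {
                        "t0_h": t0 / HOUR,
                        "tdist_h": td / HOUR,
                        "normalized_final_volume": self.normalized[i, j],
                        "clipped": bool(self.clipped[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def peak_condition(params: ModelParameters) -> bool:
    """Evaluate the published necessary condition for a pressure peak.

    The inequality ``alpha < phi * Lr * (Y - P_seed) * (phi (Y - P_seed)
    - Lr * pi_seed)`` is evaluated exactly in its printed product form.
    A peak additionally requires the fiber turgor to start below the seed
    turgor; for parameters in the biological ranges neither requirement
    holds, which is why the constant-parameter model is monotonic there.
    """
    d = peak_condition_diagnostics(params)
    return d["satisfied"]


def peak_condition_diagnostics(params: ModelParameters) -> dict:
    """Condition value plus a caveat flag.

    As printed, the right-hand side of the inequality is a product of two
    bracketed factors whose units do not reduce to those of ``alpha``
    (Pa/s); ``dimensionally_consistent`` is therefore ``False`` and the
    numerical classifier — not this screen — is the source of truth for
    behavior labels.
    """
    yp = params.Y - params.P_seed
    rhs_value = params.phi * params.Lr * yp * (params.phi * yp - params.Lr * params.pi_seed)
    return {
        "satisfied": bool(params.alpha < rhs_value),
        "rhs_value": rhs_value,
        "alpha": params.alpha,
        "dimensionally_consistent": False,
    }


def classify(
    traj: Trajectory,
    transient_fraction: float = 0.05,
    rel_guard: float = 1e-9,
) -> Dict[str, BehaviorLabel]:
    """Label each pressure trajectory from its interior extrema.

    No interior extrema (after discarding the initial transient window)
    means monotonic, with the direction taken from the endpoint comparison;
    a degenerate flat trajectory is labelled ``monotonic_increasing`` by
    convention.  A single interior maximum is a ``peak``, a single minimum a
    ``trough``, anything else ``non_monotonic_other``; the reported
    extremum time is the first extremum's.
    """
    labels: Dict[str, BehaviorLabel] = {}
    start = int(np.searchsorted(traj.t, transient_fraction * traj.t[-1]))
    for var in ("pi_fiber", "P_fiber"):
        ext = extract_extrema(traj, var, transient_fraction, rel_guard)
        y = traj.variable(var)
        if not ext:
            direction = "increasing" if y[-1] >= y[start] else "decreasing"
            labels[var] = BehaviorLabel(var, f"monotonic_{direction}")
        elif len(ext) == 1 and ext[0][2] == "max":
            labels[var] = BehaviorLabel(var, "peak", extremum_time=ext[0][0])
        elif len(ext) == 1 and ext[0][2] == "min":
            labels[var] = BehaviorLabel(var, "trough", extremum_time=ext[0][0])
        else:
            labels[var] = BehaviorLabel(var, "non_monotonic_other", extremum_time=ext[0][0])
    return labels


def _scenario_schedules(
    name: str, params: ModelParameters, alpha_high: Optional[float] = None
) -> Tuple[ParameterSchedule, ...]:
    phi_decay = ParameterSchedule("phi", "linear_decay", t_end_decay=PHI_DECAY_END)
    mu_closure = ParameterSchedule(
        "mu", "closure_window", t_start=CLOSURE_START, duration=CLOSURE_DURATION
    )
    if name == "reference":
        return ()
    if name == "phi_decay":
        return (phi_decay,)
    if name == "mu_closure":
        return (mu_closure,)
    if name == "combined":
        return (phi_decay, mu_closure)
    if name == "alpha_pulse":
        if alpha_high is None:
            alpha_high = default_table()["alpha"].x_max
        return (
            ParameterSchedule(
                "alpha",
                "pulse",
                t_start=ALPHA_PULSE_START,
                duration=ALPHA_PULSE_DURATION,
                high_value=alpha_high,
            ),
        )
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def run_scenario(
    name: str,
    base_config: Optional[SimulationConfig] = None,
    alpha_high: Optional[float] = None,
) -> ScenarioResult:
    """Run one named dynamic-parameter scenario and classify its pressures."""
    if base_config is None:
        base_config = SimulationConfig(params=reference_parameters())
    schedules = _scenario_schedules(name, base_config.params, alpha_high)
    traj = simulate(base_config.replace(schedules=schedules))
    return ScenarioResult(
        scenario=name,
        trajectory=traj,
        labels=classify(traj),
        extrema={
            var: extract_extrema(traj, var) for var in ("pi_fiber", "P_fiber")
        },
        final_volume_ratio=float(np.exp(traj.log_V[-1] - traj.log_V[0])),
    )


def closure_sweep(
    t0_grid: Optional[Sequence[float]] = None,
    tdist_grid: Optional[Sequence[float]] = None,
    base_config: Optional[SimulationConfig] = None,
    t_max: float = 3000.0 * HOUR,
    anchor: Tuple[float, float] = (200.0 * HOUR, 50.0 * HOUR),
) -> ClosureSweepResult:
    """Map final fiber volume against plasmodesmata closure start and duration.

    Each grid cell simulates to ``t_max`` with plasmodesmal permeability
    zeroed on ``[t0, t0 + tdist]``; the final volume is normalized by the
    anchor cell's (by default closure starting at 200 h lasting 50 h).
    Windows extending beyond the horizon are integrated as-is (the part
    beyond ``t_max`` is simply never reached) and flagged as clipped.
    """
    if t0_grid is None:
        t0_grid = np.arange(0.0, 501.0, 50.0) * HOUR
    if tdist_grid is None:
        tdist_grid = np.arange(0.0, 501.0, 50.0) * HOUR
    t0_grid = np.asarray(t0_grid, dtype=float)
    tdist_grid = np.asarray(tdist_grid, dtype=float)
    if base_config is None:
        base_config = SimulationConfig(params=reference_parameters())
    base_config = base_config.replace(t_max=t_max)

    def final_log_V(t0: float, tdist: float) -> float:
        sched = (
            ParameterSchedule("mu", "closure_window", t_start=t0, duration=tdist),
        )
        traj = simulate(base_config.replace(schedules=sched))
        return float(traj.log_V[-1] - traj.log_V[0])

    anchor_log = final_log_V(*anchor)
    log_ratio = np.empty((t0_grid.size, tdist_grid.size))
    clipped = np.zeros_like(log_ratio, dtype=bool)
    for i, t0 in enumerate(t0_grid):
        for j, td in enumerate(tdist_grid):
            log_ratio[i, j] = final_log_V(t0, td) - anchor_log
            clipped[i, j] = t0 + td > t_max
    return ClosureSweepResult(
        t0_grid=t0_grid,
        tdist_grid=tdist_grid,
        log_ratio=log_ratio,
        clipped=clipped,
        anchor=anchor,
    )
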