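"""Reference-value construction and parameter sensitivity statistics.

Two complementary views of parameter influence are implemented:

* the one-factor-at-a-time (OAT) sensitivity, the normalized derivative
  ``S(X, x) = (x_ref / X(x_ref)) * dX/dx`` of an observable ``X`` with
  respect to one parameter ``x`` at the reference point, estimated by a
  central finite difference; and
* the maximal change ``MC(X, x) = (max X - min X) / X(x_ref)`` as ``x``
  sweeps its whole biological range on a log-spaced grid, all other
  parameters held at reference.

The reference point itself is the geometric mean of each parameter's
biological range limits — appropriate because several ranges span many
orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Mapping, Tuple

import numpy as np
import yaml

from .model_core import ModelParameters
from .simulator import SimulationConfig, Trajectory, simulate

__all__ = [
    "PARAMETER_NAMES",
    "OBSERVABLES",
    "ParameterRange",
    "ParameterTable",
    "load_parameter_ranges",
    "build_reference",
    "default_table",
    "reference_parameters",
    "observable",
    "SensitivityReport",
    "oat_sensitivity",
    "sensitivity_table",
    "maximal_change",
]

PARAMETER_NAMES = ("Lr", "mu", "alpha", "pi_seed", "P_seed", "Y", "phi")
OBSERVABLES = ("log_volume_ratio", "pi_final", "P_final")


@dataclass(frozen=True)
class ParameterRange:
    """One parameter's biological range and derived reference value (SI)."""

    x_min: float
    x_max: float
    x_ref: float
    rel_dev_lo: float
    rel_dev_hi: float


@dataclass(frozen=True)
class ParameterTable:
    ranges: Mapping[str, ParameterRange]

    def __getitem__(self, name: str) -> ParameterRange:
        return self.ranges[name]

    def reference_values(self) -> Dict[str, float]:
        return {name: r.x_ref for name, r in self.ranges.items()}


def load_parameter_ranges() -> Dict[str, Tuple[float, float]]:
    """Packaged biological ranges, as ``{name: (x_min, x_max)}`` in SI units."""
    text = resources.files("fibersim").joinpath("data/parameter_ranges.yaml").read_text()
    raw = yaml.safe_load(text)["parameters"]
    return {name: (float(d["min"]), float(d["max"])) for name, d in raw.items()}


def build_reference(ranges: Mapping[str, Tuple[float, float]]) -> ParameterTable:
    """Derive reference values (geometric means) and relative deviations.

    Raises on non-positive or inverted ranges; a degenerate range
    ``[a, a]`` is allowed and yields reference ``a`` with zero deviations.
    """
    table = {}
    for name, (lo, hi) in ranges.items():
        if not (0.0 < lo <= hi):
            raise ValueError(f"range for {name} must satisfy 0 < min <= max, got [{lo}, {hi}]")
        x_ref = math.sqrt(lo * hi)
        table[name] = ParameterRange(
            x_min=lo,
            x_max=hi,
            x_ref=x_ref,
            rel_dev_lo=lo / x_ref - 1.0,
            rel_dev_hi=hi / x_ref - 1.0,
        )
    return ParameterTable(ranges=table)


def default_table() -> ParameterTable:
    """Reference table built from the packaged biological ranges."""
    return build_reference(load_parameter_ranges())


def reference_parameters(table: ParameterTable | None = None) -> ModelParameters:
    """Model parameters at the reference point (geometric means of the ranges)."""
    table = table if table is not None else default_table()
    return ModelParameters(**{name: table[name].x_ref for name in PARAMETER_NAMES})


def observable(traj: Trajectory, which: str) -> float:
    """Scalar observable of a finished run.

    ``log_volume_ratio`` is ``ln(V(t_max)/V(0))`` (computed from the carried
    log-volume so extreme growth cannot overflow); the pressure observables
    are final-time values in Pa.
    """
    if which == "log_volume_ratio":
        return float(traj.log_V[-1] - traj.log_V[0])
    if which == "pi_final":
        return float(traj.pi_fiber[-1])
    if which == "P_final":
        return float(traj.P_fiber[-1])
    raise ValueError(f"unknown observable {which!r}; choose from {OBSERVABLES}")


@dataclass(frozen=True)
class SensitivityReport:
    """Central-difference OAT sensitivity with the evidence behind it."""

    observable: str
    parameter: str
    S: float
    step_fraction: float
    X_ref: float
    X_plus: float
    X_minus: float

    @property
    def S_forward(self) -> float:
        return (self.X_plus - self.X_ref) / (self.step_fraction * self.X_ref)

    @property
    def S_backward(self) -> float:
        return (self.X_ref - self.X_minus) / (self.step_fraction * self.X_ref)


def _run_observable(config: SimulationConfig, params: ModelParameters, which: str) -> float:
    return observable(simulate(config.replace(params=params)), which)


def oat_sensitivity(
    config: SimulationConfig,
    table: ParameterTable,
    observable_name: str,
    parameter: str,
    step_fraction: float = 0.01,
    X_ref: float | None = None,
) -> SensitivityReport:
    """One-factor-at-a-time sensitivity of one observable to one parameter.

    ``S = [X(x_ref (1+h)) - X(x_ref (1-h))] / (2 h X(x_ref))`` with
    ``h = step_fraction``; all other parameters stay at reference, and the
    exploration never leaves the +/-10% window around the reference value.
    When the perturbed parameter is ``pi_seed`` and the configuration uses
    the standard initial condition, the initial fiber osmotic pressure
    follows the perturbed seed value (the initial condition is defined as
    equal to it).

    ``X_ref`` may be supplied to reuse a previously computed reference run.
    """
    if not (0.0 < step_fraction <= 0.1):
        raise ValueError("step_fraction must be in (0, 0.1]")
    if parameter not in PARAMETER_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    x_ref = table[parameter].x_ref
    base = config.params.replace(**{parameter: x_ref})
    if X_ref is None:
        X_ref = _run_observable(config, base, observable_name)
    if X_ref == 0.0:
        raise ZeroDivisionError(
            f"observable {observable_name!r} is zero at reference; S undefined"
        )
    h = step_fraction
    X_plus = _run_observable(config, base.replace(**{parameter: x_ref * (1 + h)}), observable_name)
    X_minus = _run_observable(config, base.replace(**{parameter: x_ref * (1 - h)}), observable_name)
    return SensitivityReport(
        observable=observable_name,
        parameter=parameter,
        S=(X_plus - X_minus) / (2.0 * h * X_ref),
        step_fraction=h,
        X_ref=X_ref,
        X_plus=X_plus,
        X_minus=X_minus,
    )


def sensitivity_table(
    config: SimulationConfig,
    table: ParameterTable | None = None,
    step_fraction: float = 0.01,
):
    """Full OAT sensitivity matrix: observables as rows, parameters as columns.

    Shares one reference run across all entries.  Returns a pandas
    DataFrame indexed by observable name.
    """
    import pandas as pd

    table = table if table is not None else default_table()
    base = reference_parameters(table)
    ref_traj = simulate(config.replace(params=base))
    rows = {}
    for obs in OBSERVABLES:
        X_ref = observable(ref_traj, obs)
        rows[obs] = {
            p: oat_sensitivity(config, table, obs, p, step_fraction, X_ref=X_ref).S
            for p in PARAMETER_NAMES
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(PARAMETER_NAMES)]


def maximal_change(
    config: SimulationConfig,
    table: ParameterTable,
    observable_name: str,
    parameter: str,
    n_grid: int = 33,
) -> float:
    """Maximal change of an observable over one parameter's biological range.

    The parameter sweeps a log-spaced grid of ``n_grid`` values spanning
    ``[x_min, x_max]`` (endpoints included, so monotone observables get
    their exact extremes); the result is the observable's range normalized
    by its reference value, non-negative by construction.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    r = table[parameter]
    base = config.params.replace(**{parameter: r.x_ref})
    X_ref = _run_observable(config, base, observable_name)
    if X_ref == 0.0:
        raise ZeroDivisionError(
            f"observable {observable_name!r} is zero at reference; MC undefined"
        )
    grid = np.geomspace(r.x_min, r.x_max, n_grid)
    values = [
        _run_observable(config, base.replace(**{parameter: float(x)}), observable_name)
        for x in grid
    ]
    return (max(values) - min(values)) / X_ref
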