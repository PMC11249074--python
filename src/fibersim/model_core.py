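"""Algebraic core of the fiber elongation model.

The growing cotton fiber is treated as a single cylindrical cell exchanging
water with the apoplast across its plasma membrane and with the seed-coat
symplast through plasmodesmata.  Volume changes are purely hydraulic
(water is incompressible), irreversible wall expansion follows the Lockhart
law with yield threshold ``Y`` and extensibility ``phi``, and the fiber
turgor is eliminated algebraically by balancing the wall-expansion rate
against the total water influx.  What remains is a two-variable dynamical
system in fiber volume ``V`` and fiber osmotic pressure ``pi_fiber``.

All quantities are strict SI internally: volumes in m^3, pressures in Pa,
times in s.  Unit conversion happens only at the I/O boundary
(:mod:`fibersim.cli_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

__all__ = [
    "ModelParameters",
    "FiberState",
    "DerivedQuantities",
    "delta_P",
    "flux_membrane",
    "flux_plasmodesmata",
    "growth_rate",
    "derived_quantities",
    "rhs",
]


@dataclass(frozen=True)
class ModelParameters:
    """The seven physical parameters of the fiber model (SI units).

    Attributes
    ----------
    Lr : float
        Relative hydraulic conductivity of the plasma membrane, Pa^-1 s^-1.
        Absorbs the per-area permeability and fiber radius (membrane area is
        proportional to volume for a long cylinder).
    mu : float
        Total plasmodesmal permeability, m^3 Pa^-1 s^-1.  Zero means closed
        plasmodesmata.
    alpha : float
        Normalized solute source rate (uptake + synthesis), Pa s^-1.
    pi_seed : float
        Osmotic pressure of the seed-coat symplast, Pa.
    P_seed : float
        Turgor pressure of the seed coat, Pa.
    Y : float
        Lockhart yield threshold: turgor below which no irreversible wall
        expansion occurs, Pa.
    phi : float
        Cell wall extensibility (inverse effective wall viscosity),
        Pa^-1 s^-1.
    """

    Lr: float
    mu: float
    alpha: float
    pi_seed: float
    P_seed: float
    Y: float
    phi: float

    def __post_init__(self) -> None:
        for name in ("Lr", "mu", "alpha", "pi_seed", "P_seed", "Y", "phi"):
            value = getattr(self, name)
            if not value >= 0.0:
                raise ValueError(f"parameter {name} must be >= 0, got {value!r}")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class FiberState:
    """Instantaneous state of the fiber: volume (m^3) and osmotic pressure (Pa)."""

    V: float
    pi_fiber: float

    def __post_init__(self) -> None:
        if not self.V > 0.0:
            raise ValueError(f"volume must be > 0, got {self.V!r}")
        if not self.pi_fiber >= 0.0:
            raise ValueError(f"pi_fiber must be >= 0, got {self.pi_fiber!r}")


@dataclass(frozen=True)
class DerivedQuantities:
    """Quantities derived from a (parameters, state) pair.

    ``dP`` is the fiber-minus-seed turgor difference, ``P_fiber`` the fiber
    turgor, ``F_m`` and ``F_p`` the water fluxes through the membrane and
    through plasmodesmata (positive into the fiber), and ``rgr`` the relative
    growth rate (1/V) dV/dt, which is non-negative because wall expansion is
    irreversible.
    """

    dP: float
    P_fiber: float
    F_m: float
    F_p: float
    rgr: float


def delta_P(params: ModelParameters, state: FiberState) -> float:
    """Turgor difference ``P_fiber - P_seed`` with turgor eliminated algebraically.

    Balancing total water influx against the Lockhart expansion rate gives a
    piecewise-linear closed form in the osmotic difference
    ``dpi = pi_fiber - pi_seed``:

    - no-growth branch: ``dP = dpi / (1 + mu/(Lr V))`` whenever this value is
      below ``Y - P_seed`` (fiber turgor under the yield threshold);
    - growth branch: ``dP = (dpi + (phi/Lr)(Y - P_seed)) /
      (1 + mu/(Lr V) + phi/Lr)`` otherwise.

    The two branches agree exactly on the switching surface, so ``dP`` is
    continuous (though not smooth) in the state.

    Raises
    ------
    ValueError
        If ``Lr == 0`` or ``V == 0`` (the normalized form divides by both;
        a membrane with zero conductivity is outside the model's scope).
    """
    if params.Lr == 0.0:
        raise ValueError("delta_P undefined for Lr = 0 (zero membrane conductivity)")
    if state.V == 0.0:
        raise ValueError("delta_P undefined for V = 0")
    dpi = state.pi_fiber - params.pi_seed
    hydraulic = 1.0 + params.mu / (params.Lr * state.V)
    no_growth = dpi / hydraulic
    threshold = params.Y - params.P_seed
    if no_growth < threshold:
        return no_growth
    return (dpi + (params.phi / params.Lr) * threshold) / (
        hydraulic + params.phi / params.Lr
    )


def flux_membrane(params: ModelParameters, state: FiberState, dP: float) -> float:
    """Water flux through the plasma membrane, m^3/s (positive into the fiber).

    ``F_m = Lr V (dpi - dP)``: the membrane flux is driven by the water
    potential difference between fiber and apoplast, with the seed-coat
    symplast at equilibrium with the apoplast.
    """
    dpi = state.pi_fiber - params.pi_seed
    return params.Lr * state.V * (dpi - dP)


def flux_plasmodesmata(params: ModelParameters, dP: float) -> float:
    """Water flux through plasmodesmata, ``F_p = -mu dP`` (m^3/s).

    Positive when the seed turgor exceeds the fiber turgor (bulk flow into
    the fiber).
    """
    return -params.mu * dP


def growth_rate(params: ModelParameters, dP: float) -> float:
    """Relative growth rate ``phi * (P_fiber - Y)_+`` in s^-1.

    Exactly zero when fiber turgor is at or below the yield threshold;
    irreversible expansion never shrinks the cell.
    """
    return params.phi * max(dP + params.P_seed - params.Y, 0.0)


def derived_quantities(params: ModelParameters, state: FiberState) -> DerivedQuantities:
    """Evaluate all derived quantities at a (parameters, state) pair."""
    dP = delta_P(params, state)
    return DerivedQuantities(
        dP=dP,
        P_fiber=dP + params.P_seed,
        F_m=flux_membrane(params, state, dP),
        F_p=flux_plasmodesmata(params, dP),
        rgr=growth_rate(params, dP),
    )


def rhs(params: ModelParameters, state: FiberState) -> Tuple[float, float]:
    """Right-hand side of the two-variable system: (dV/dt, dpi_fiber/dt).

    ``dV/dt = rgr * V`` (identical to ``F_m + F_p`` by construction of
    :func:`delta_P`; the growth-law form is used to avoid double round-off).

    The osmotic pressure obeys

    ``dpi/dt = alpha - (pi/V) dV/dt + mu (pi_seed/V) (-dP)_+
               - mu (pi/V) (dP)_+``

    i.e. a constant source, dilution by growth, and advection of solutes
    through plasmodesmata carrying the upstream concentration (seed
    concentration on inflow, fiber concentration on outflow), all expressed
    as osmotic pressures.
    """
    dP = delta_P(params, state)
    dV_dt = growth_rate(params, dP) * state.V
    pi = state.pi_fiber
    dpi_dt = (
        params.alpha
        - (pi / state.V) * dV_dt
        + params.mu * (params.pi_seed / state.V) * max(-dP, 0.0)
        - params.mu * (pi / state.V) * max(dP, 0.0)
    )
    return dV_dt, dpi_dt
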