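"""Algebraic core: piecewise turgor difference, fluxes, growth law, RHS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from fibersim.model_core import (
    FiberState,
    ModelParameters,
    delta_P,
    derived_quantities,
    flux_membrane,
    flux_plasmodesmata,
    growth_rate,
    rhs,
)

V0 = 1.88e-13


def make_params(**overrides):
    base = dict(
        Lr=1.58e-7, mu=6.67e-23, alpha=118.0, pi_seed=1.13e6,
        P_seed=1.12e5, Y=1.10e5, phi=5.24e-12,
    )
    base.update(overrides)
    return ModelParameters(**base)


def flux_balance_root(params, state):
    """Independent oracle: bisection root of the water balance.

    The turgor difference must satisfy
    ``phi V (dP + P_seed - Y)_+ = Lr V (dpi - dP) - mu dP``
    (wall expansion consumes exactly the water that enters); the left side
    is non-decreasing and the right side strictly decreasing in dP, so the
    root is unique and bracketed by ``+/- (|dpi| + |Y - P_seed| + 1)``.
    """
    dpi = state.pi_fiber - params.pi_seed

    def g(dP):
        growth = params.phi * state.V * max(dP + params.P_seed - params.Y, 0.0)
        return params.Lr * state.V * (dpi - dP) - params.mu * dP - growth

    hi = abs(dpi) + abs(params.Y - params.P_seed) + 1.0
    return bisect(g, -hi, hi, xtol=1e-18 * hi, maxiter=300)


class TestDeltaP:
    def test_closed_plasmodesmata_below_yield_gives_classical_no_growth(self):
        # mu = 0 and fiber turgor under the yield threshold: dP = dpi exactly
        params = make_params(mu=0.0, P_seed=1.0e5, Y=2.0e5)
        dpi = 0.5 * (params.Y - params.P_seed)
        state = FiberState(V=V0, pi_fiber=params.pi_seed + dpi)
        assert delta_P(params, state) == dpi

    def test_zero_extensibility_makes_branches_coincide(self):
        params = make_params(phi=0.0)
        for pi in (0.5e6, 1.13e6, 3.0e6):
            state = FiberState(V=V0, pi_fiber=pi)
            dpi = pi - params.pi_seed
            expected = dpi / (1.0 + params.mu / (params.Lr * state.V))
            assert delta_P(params, state) == pytest.approx(expected, rel=1e-14)

    def test_growth_branch_matches_bisection_root_at_reference_state(self, ref_params):
        state = FiberState(V=V0, pi_fiber=ref_params.pi_seed)
        root = flux_balance_root(ref_params, state)
        assert delta_P(ref_params, state) == pytest.approx(root, rel=1e-10, abs=1e-10)

    def test_branches_agree_on_switching_surface(self):
        # tune dpi so the no-growth expression lands exactly on Y - P_seed
        params = make_params(P_seed=1.0e5, Y=1.5e5)
        hydraulic = 1.0 + params.mu / (params.Lr * V0)
        dpi = (params.Y - params.P_seed) * hydraulic
        no_growth = dpi / hydraulic
        growth = (dpi + (params.phi / params.Lr) * (params.Y - params.P_seed)) / (
            hydraulic + params.phi / params.Lr
        )
        assert growth == pytest.approx(no_growth, rel=1e-12)

    def test_zero_membrane_conductivity_rejected(self):
        params = make_params(Lr=0.0)
        with pytest.raises(ValueError):
            delta_P(params, FiberState(V=V0, pi_fiber=1.13e6))


@pytest.mark.parametrize(
    "fn, args, expected",
    [
        # unit arithmetic straight from the flux/growth definitions
        (flux_membrane, (make_params(Lr=1e-7, pi_seed=0.0), FiberState(V=1e-13, pi_fiber=1e6), 0.0), 1e-14),
        (flux_plasmodesmata, (make_params(mu=6.67e-23), 1e5), -6.67e-18),
        (growth_rate, (make_params(phi=5.3e-12, P_seed=0.0, Y=0.0), 1e5), 5.3e-7),
    ],
)
def test_flux_and_growth_unit_arithmetic(fn, args, expected):
    assert fn(*args) == pytest.approx(expected, rel=1e-12)


def test_membrane_flux_vanishes_at_water_potential_equilibrium():
    params = make_params()
    state = FiberState(V=V0, pi_fiber=1.5e6)
    dpi = state.pi_fiber - params.pi_seed
    assert flux_membrane(params, state, dP=dpi) == 0.0


def test_plasmodesmal_flux_zero_when_closed_or_equilibrated():
    assert flux_plasmodesmata(make_params(mu=0.0), 1e5) == 0.0
    assert flux_plasmodesmata(make_params(), 0.0) == 0.0


def test_growth_rate_positive_part():
    params = make_params(P_seed=1.0e5, Y=2.0e5)
    assert growth_rate(params, dP=params.Y - params.P_seed) == 0.0  # at threshold
    assert growth_rate(params, dP=0.0) == 0.0  # below threshold
    assert growth_rate(params, dP=2e5) > 0.0


class TestRHS:
    def test_full_equilibrium_is_stationary(self):
        # alpha = 0, pi = pi_seed, no growth possible: both derivatives vanish
        params = make_params(alpha=0.0, P_seed=1.0e5, Y=2.0e5)
        state = FiberState(V=V0, pi_fiber=params.pi_seed)
        assert rhs(params, state) == (0.0, 0.0)

    def test_closed_plasmodesmata_leaves_only_source_and_dilution(self):
        params = make_params(mu=0.0)
        state = FiberState(V=V0, pi_fiber=2.0e6)
        dV_dt, dpi_dt = rhs(params, state)
        assert dpi_dt == params.alpha - (state.pi_fiber / state.V) * dV_dt

    def test_volume_rate_equals_total_flux_at_reference(self, ref_params):
        state = FiberState(V=V0, pi_fiber=ref_params.pi_seed)
        dV_dt, _ = rhs(ref_params, state)
        d = derived_quantities(ref_params, state)
        scale = max(abs(dV_dt), abs(d.F_m), abs(d.F_p))
        assert abs(dV_dt - (d.F_m + d.F_p)) <= 10 * np.finfo(float).eps * scale


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    log_Lr=st.floats(math.log10(5e-9), math.log10(5e-6)),
    log_mu=st.floats(math.log10(1.35e-26), math.log10(3.3e-19)),
    alpha=st.floats(83.0, 167.0),
    pi_seed=st.floats(0.99e6, 1.29e6),
    P_seed=st.floats(0.07e6, 0.18e6),
    Y=st.floats(0.06e6, 0.20e6),
    log_phi=st.floats(math.log10(1.1e-12), math.log10(2.5e-11)),
    log_V=st.floats(-14.0, -11.0),
    pi_scale=st.floats(0.2, 3.0),
)
def test_water_balance_identity_over_biological_ranges(
    log_Lr, log_mu, alpha, pi_seed, P_seed, Y, log_phi, log_V, pi_scale
):
    """rgr * V == F_m + F_p for any parameters/state in the biological ranges."""
    params = ModelParameters(
        Lr=10**log_Lr, mu=10**log_mu, alpha=alpha,
        pi_seed=pi_seed, P_seed=P_seed, Y=Y, phi=10**log_phi,
    )
    state = FiberState(V=10**log_V, pi_fiber=pi_scale * pi_seed)
    d = derived_quantities(params, state)
    total = d.F_m + d.F_p
    # the identity holds to rounding relative to the gross flux magnitude
    # Lr V |dpi|: F_m and F_p can cancel almost exactly (no-growth branch),
    # so the net flux itself is not the right scale
    gross = params.Lr * state.V * (abs(state.pi_fiber - pi_seed) + 1.0)
    scale = max(abs(d.F_m), abs(d.F_p), abs(d.rgr * state.V), gross)
    assert abs(d.rgr * state.V - total) <= 1e-12 * scale
    assert d.rgr >= 0.0


def test_increasing_mu_weakly_reduces_net_influx_when_fiber_pressurized():
    """With fiber turgor above seed turgor, opening plasmodesmata bleeds the
    fiber toward the seed: total water influx is non-increasing in mu."""
    state = FiberState(V=V0, pi_fiber=2.5e6)
    fluxes = []
    for mu in np.geomspace(1e-26, 1e-19, 12):
        params = make_params(mu=mu)
        d = derived_quantities(params, state)
        assert d.dP > 0
        fluxes.append(d.F_m + d.F_p)
    assert all(b <= a + 1e-25 for a, b in zip(fluxes, fluxes[1:]))


def test_solute_source_shifts_pi_rate_by_exactly_its_increment():
    params = make_params()
    state = FiberState(V=V0, pi_fiber=1.5e6)
    _, dpi1 = rhs(params, state)
    _, dpi2 = rhs(params.replace(alpha=params.alpha + 25.0), state)
    assert dpi2 - dpi1 == pytest.approx(25.0, rel=1e-12)


def test_parameter_and_state_invariants_enforced():
    with pytest.raises(ValueError):
        make_params(alpha=-1.0)
    with pytest.raises(ValueError):
        FiberState(V=0.0, pi_fiber=1e6)
    with pytest.raises(ValueError):
        FiberState(V=1e-13, pi_fiber=-1.0)
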