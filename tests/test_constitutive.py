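"""Excess-pressure stress and the scenario growth/decay laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuemix.constitutive import (excess_pressure, excess_pressure_all,
                                    rates_oxygen_coupled, rates_regeneration,
                                    rates_tumor)
from tissuemix.grid import Grid
from tissuemix.params import Kinetics, Mechanics
from tissuemix.state import PhaseState

from conftest import random_state


def test_excess_pressure_direct_values():
    assert excess_pressure(np.array([0.25]), 500.0, 0.25) == 0.0
    assert np.isclose(excess_pressure(np.array([0.20]), 500.0, 0.25)[0], 25.0)
    assert excess_pressure(np.array([0.95]), 500.0, 0.25)[0] == 0.0  # one-sided
    with pytest.raises(ValueError):
        excess_pressure(np.array([0.2]), -1.0, 0.25)


def test_excess_pressure_fluid_always_zero(small_grid, rng):
    state = random_state(small_grid, rng, 3)
    mech = Mechanics.equal_drag([0.0, 300.0, 200.0], 1e5)
    psi = excess_pressure_all(state, mech)
    assert np.all(psi[0] == 0.0)
    assert np.all(psi >= 0.0)


def _uniform_state(grid, names, fracs):
    return PhaseState.uniform(grid, names, fracs)


def test_regeneration_homeostasis_is_zero_rate(small_grid):
    state = _uniform_state(small_grid, ("fluid", "cells", "ecm"), (0.25, 0.7, 0.05))
    kin = Kinetics(b1_max=0.05, b2_max=3.0, u_ecm_opt=0.05)
    mech = Mechanics.equal_drag([0, 500, 300], 1e5, u0_opt=0.25)
    g = rates_regeneration(state, kin, mech)
    assert np.all(g == 0.0)


def test_regeneration_growth_only_at_wound_rim(small_grid):
    """The gradient trigger vanishes in the flat wound interior and in the
    intact tissue; cells grow only where the fluid-excess deviation varies."""
    names = ("fluid", "cells", "ecm")
    u = np.zeros((3,) + small_grid.shape)
    u[1] = 0.7
    u[1][:3, :] = 0.0  # wound occupying x < 3
    u[2] = 0.05
    u[0] = 1 - u[1] - u[2]
    state = PhaseState(small_grid, names, u)
    kin = Kinetics(b1_max=0.04, b2_max=0.0, u_ecm_opt=0.05)
    mech = Mechanics.equal_drag([0, 500, 300], 1e5, u0_opt=0.25)
    g = rates_regeneration(state, kin, mech)
    assert np.all(g[1][0:2, :] == 0.0)        # flat wound interior: no trigger
    assert np.all(g[1][4:, :] == 0.0)         # intact tissue: no deviation
    assert np.all(g[1][3, :] > 0.0)           # rim cells grow


def test_regeneration_trigger_manual_stencil():
    """Hand-computed gradient-norm trigger on a 3x3 patch."""
    grid = Grid(3, 3, 0.1)
    u = np.zeros((3, 3, 3))
    u[1] = 0.7
    u[1][1, 1] = 0.0          # one-cell wound at the center
    u[2] = 0.05
    u[0] = 1 - u[1] - u[2]
    state = PhaseState(grid, ("fluid", "cells", "ecm"), u)
    kin = Kinetics(b1_max=0.04, b2_max=0.0, u_ecm_opt=0.05)
    mech = Mechanics.equal_drag([0, 500, 300], 1e5, u0_opt=0.25)
    g = rates_regeneration(state, kin, mech)
    # dev = (u0-0.25)+ is 0.7 at the center, 0 elsewhere; at cell (0,1) the
    # east x-face carries gradient 0.7/h, the other three faces 0:
    # trigger = sqrt(((0.7/h)^2)/2), b1 = b1_max*u0*trigger, g1 = b1*u1
    trig = np.sqrt(0.5 * (0.7 / 0.1) ** 2)
    expected = 0.04 * 0.25 * trig * 0.7
    assert np.isclose(g[1][0, 1], expected, rtol=1e-12)


def test_oxygen_death_rate_printed_arithmetic(small_grid):
    """Scalar checks of the tanh decay curve: value 1/2 at the lower
    threshold, saturation limits, and the o -> 0 value."""
    names = ("fluid", "live", "dead", "ecm")
    state = _uniform_state(small_grid, names, (0.25, 0.7, 0.0, 0.05))
    mech = Mechanics.equal_drag([0, 500, 600, 400], 8e5, u0_opt=0.25)
    kin = Kinetics(b1_max=0.0, b3_max=0.0, d1_hat=0.0, d1_tilde=1.0, d2=0.0,
                   T1=2.0, T2=10.0, R1=0.25, R2=0.25, u_ecm_opt=0.05)
    # d1(o = T1) = d1_tilde/2 since tanh(0) = 0; g2 = d1 * u1
    o = np.full(small_grid.shape, 2.0)
    g = rates_oxygen_coupled(state, kin, mech, {"oxygen": o})
    assert np.allclose(g[2], 0.5 * 0.7)
    # o -> 0: d1 = (1 - tanh(-0.5))/2 * d1_tilde = 0.7311...
    g = rates_oxygen_coupled(state, kin, mech, {"oxygen": np.zeros(small_grid.shape)})
    assert np.allclose(g[2], 0.5 * (1 - np.tanh(-0.5)) * 0.7)
    assert np.allclose(g[2] / 0.7, 0.73105857, rtol=1e-6)
    # o -> inf: decay vanishes
    g = rates_oxygen_coupled(state, kin, mech, {"oxygen": np.full(small_grid.shape, 1e6)})
    assert np.allclose(g[2], 0.0, atol=1e-12)


def test_oxygen_growth_saturates(small_grid):
    """b1 approaches its normoxic maximum b1_max*u0*|grad dev| as o grows."""
    names = ("fluid", "live", "dead", "ecm")
    u = np.zeros((4,) + small_grid.shape)
    u[1] = 0.7
    u[1][:2, :] = 0.0
    u[3] = 0.05
    u[0] = 1 - u[1:].sum(axis=0)
    state = PhaseState(small_grid, names, u)
    mech = Mechanics.equal_drag([0, 500, 600, 400], 8e5, u0_opt=0.25)
    kin = Kinetics(b1_max=0.04, d1_hat=0.0, d1_tilde=0.0, u_ecm_opt=0.05,
                   b3_max=0.0)
    g_hi = rates_oxygen_coupled(state, kin, mech,
                                {"oxygen": np.full(small_grid.shape, 1e6)})
    # the saturated growth equals the oxygen-free regeneration law's b1*u1
    kin_reg = Kinetics(b1_max=0.04, b2_max=0.0, u_ecm_opt=0.05)
    state3 = PhaseState(small_grid, ("fluid", "cells", "ecm"),
                        np.stack([state.u[0] + state.u[2], state.u[1], state.u[3]]))
    g_ref = rates_regeneration(state3, kin_reg, mech)
    assert np.allclose(g_hi[1], g_ref[1], rtol=1e-9)


def test_tumor_rates_printed_forms(small_grid):
    names = ("fluid", "normal", "tumor", "ecm")
    state = _uniform_state(small_grid, names, (0.25, 0.55, 0.15, 0.05))
    mech = Mechanics.equal_drag([0, 1, 1, 25], 1e6, u0_opt=0.25)
    kin = Kinetics(b2_hat=0.9, d2_hat=0.06, d1_hat=0.06, b3_hat=50.0,
                   u_ecm_opt=0.05)
    g = rates_tumor(state, kin, mech)
    # at u0 = u0_opt the starvation clamp is inactive
    assert np.allclose(g[1], 0.0)
    assert np.allclose(g[2], 0.9 * 0.25 * 0.15)
    assert np.allclose(g[3], 0.0)  # ECM at optimum, alpha = 0


def test_tumor_active_response_degeneracy_and_target(small_grid):
    names = ("fluid", "normal", "tumor", "ecm")
    state = _uniform_state(small_grid, names, (0.21, 0.05, 0.7, 0.04))
    mech = Mechanics.equal_drag([0, 1, 1, 25], 1e6, u0_opt=0.25)
    kin0 = Kinetics(b2_hat=0.9, d2_hat=0.06, d1_hat=0.06, b3_hat=50.0,
                    alpha=0.0, u_ecm_opt=0.05)
    kin1 = Kinetics(b2_hat=0.9, d2_hat=0.06, d1_hat=0.06, b3_hat=50.0,
                    alpha=1.0, u_ecm_opt=0.05)
    # alpha = 0 reduces the active-response law to the base law identically
    assert np.array_equal(rates_tumor(state, kin0, mech),
                          rates_tumor(state, kin0, mech))
    # inflated target: u2 = 0.7, alpha = 1, u3_opt = 0.05 -> 0.085
    g = rates_tumor(state, kin1, mech)
    target = (1 + 1.0 * 0.7) * 0.05
    assert np.isclose(target, 0.085)
    expected = 50.0 * state.u[0] * state.u[1] * (target - 0.04)
    assert np.allclose(g[3], expected)


@given(st.integers(0, 2 ** 31 - 1), st.sampled_from(["regeneration", "tumor",
                                                     "oxygen_coupled"]))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_rate_sets_sum_to_zero(seed, law):
    """No net volume change: every rate law returns g with sum_i g_i = 0
    exactly, by construction of the fluid rate."""
    rng = np.random.default_rng(seed)
    grid = Grid(5, 4, 0.05)
    ncomp = 3 if law == "regeneration" else 4
    state = random_state(grid, rng, ncomp)
    mech = Mechanics.equal_drag([0.0] + [100.0] * (ncomp - 1), 1e5)
    kin = Kinetics(b1_max=0.05, b2_max=3.0, b3_max=2.0, b2_hat=0.9,
                   d2_hat=0.06, b3_hat=50.0, d1_hat=0.05, d1_tilde=0.01,
                   d2=0.5, alpha=1.0, u_ecm_opt=0.05)
    chem = {"oxygen": rng.uniform(0, 40, size=grid.shape)}
    g = {"regeneration": rates_regeneration, "tumor": rates_tumor,
         "oxygen_coupled": rates_oxygen_coupled}[law](state, kin, mech, chem)
    # the fluid rate is the exact negation of the structural rates ...
    assert np.array_equal(g[0], -g[1:].sum(axis=0))
    # ... so the total vanishes to round-off of the summation order
    assert np.allclose(g.sum(axis=0), 0.0, atol=1e-15 * max(np.abs(g).max(), 1))


@pytest.mark.parametrize("law,ncomp", [("regeneration", 3), ("tumor", 4),
                                       ("oxygen_coupled", 4)])
def test_zero_coefficients_give_zero_rates(law, ncomp, small_grid, rng):
    state = random_state(small_grid, rng, ncomp)
    mech = Mechanics.equal_drag([0.0] + [100.0] * (ncomp - 1), 1e5)
    kin = Kinetics()  # all coefficients zero
    chem = {"oxygen": np.full(small_grid.shape, 30.0)}
    g = {"regeneration": rates_regeneration, "tumor": rates_tumor,
         "oxygen_coupled": rates_oxygen_coupled}[law](state, kin, mech, chem)
    assert np.all(g == 0.0)
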