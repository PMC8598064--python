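"""Momentum-closure flux solver against independent dense oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuemix.constitutive import excess_pressure_all
from tissuemix.grid import Grid, gradient_faces
from tissuemix.momentum import (assemble_local_system, pressure_gradient,
                                solve_fluxes)
from tissuemix.params import Mechanics
from tissuemix.state import PhaseState

from conftest import random_mechanics, random_state


def global_oracle(state, mech):
    """Independent oracle: at every interior face solve the full
    pre-elimination system — one drag-balance row per non-fluid component in
    the flux variables q_j = u_j v_j plus the zero-net-flux row — by a dense
    solve, without the fluid-elimination algebra of the production solver.
    """
    grid = state.grid
    ncomp = state.ncomp
    psi = excess_pressure_all(state, mech)
    uP = state.u * psi
    h = grid.h
    qx = np.zeros((ncomp, grid.nx + 1, grid.ny))
    qy = np.zeros((ncomp, grid.nx, grid.ny + 1))

    def solve_face(u_f, grad):
        # rows i = 1..n+1: sum_j a_ij (u_i q_j - u_j q_i) = grad(u_i P_i) - u_i grad(S)
        # + closing row sum_j q_j = 0
        A = np.zeros((ncomp, ncomp))
        b = np.zeros(ncomp)
        S = grad.sum()
        for i in range(1, ncomp):
            for j in range(ncomp):
                if j == i:
                    A[i - 1, i] -= sum(mech.drag[i, m] * u_f[m]
                                       for m in range(ncomp) if m != i)
                else:
                    A[i - 1, j] += mech.drag[i, j] * u_f[i]
            b[i - 1] = grad[i] - u_f[i] * S
        A[ncomp - 1, :] = 1.0
        b[ncomp - 1] = 0.0
        return np.linalg.solve(A, b)

    for fi in range(1, grid.nx):
        for j in range(grid.ny):
            u_f = 0.5 * (state.u[:, fi, j] + state.u[:, fi - 1, j])
            grad = (uP[:, fi, j] - uP[:, fi - 1, j]) / h
            qx[:, fi, j] = solve_face(u_f, grad)
    for i in range(grid.nx):
        for fj in range(1, grid.ny):
            u_f = 0.5 * (state.u[:, i, fj] + state.u[:, i, fj - 1])
            grad = (uP[:, i, fj] - uP[:, i, fj - 1]) / h
            qy[:, i, fj] = solve_face(u_f, grad)
    return qx, qy


def test_local_system_pure_fluid():
    """Only fluid present: diagonal system with zero right-hand side."""
    u_face = np.array([1.0, 0.0, 0.0])
    drag = np.array([[0, 2e5, 3e5], [2e5, 0, 4e5], [3e5, 4e5, 0.0]])
    A, r = assemble_local_system(u_face, np.zeros(2), drag)
    assert np.allclose(A, np.diag([2e5, 3e5]))
    assert np.allclose(r, 0.0)
    assert np.allclose(np.linalg.solve(A, r), 0.0)


def test_local_system_equal_drag_decouples():
    """With equal drags the off-diagonals vanish and, since the face
    fractions sum to one, the matrix is alpha_hat times identity."""
    u_face = np.array([0.25, 0.45, 0.30])
    a = 5e5
    drag = np.full((3, 3), a)
    np.fill_diagonal(drag, 0.0)
    grad = np.array([3.0, -1.0])
    A, r = assemble_local_system(u_face, grad, drag)
    assert np.allclose(A, a * np.eye(2))
    S = grad.sum()
    assert np.allclose(r, u_face[1:] * S - grad)


def test_two_phase_closed_form(small_grid, rng):
    """Fluid + one component with equal drag: q1 = -u0 grad(u1 Psi1)/alpha."""
    u1 = rng.uniform(0.1, 0.7, size=small_grid.shape)
    u = np.stack([1 - u1, u1])
    state = PhaseState(small_grid, ("fluid", "cells"), u)
    a = 3e5
    mech = Mechanics.equal_drag([0.0, 400.0], a, u0_opt=0.6)
    flux = solve_fluxes(state, mech)
    psi = excess_pressure_all(state, mech)
    g = gradient_faces(small_grid, state.u[1] * psi[1])
    u0f_x = 0.5 * (state.u[0][1:, :] + state.u[0][:-1, :])
    expected = -u0f_x * g.x[1:-1, :] / a
    assert np.allclose(flux.x[1, 1:-1, :], expected, rtol=1e-12, atol=1e-18)


@pytest.mark.parametrize("ncomp", [2, 3, 4])
@pytest.mark.parametrize("equal_drag", [True, False])
def test_matches_global_dense_oracle(ncomp, equal_drag, rng):
    grid = Grid(4, 5, 0.1)
    state = random_state(grid, rng, ncomp)
    mech = random_mechanics(rng, ncomp, equal_drag)
    flux = solve_fluxes(state, mech)
    qx, qy = global_oracle(state, mech)
    scale = max(np.abs(qx).max(), np.abs(qy).max(), 1e-30)
    assert np.allclose(flux.x, qx, rtol=1e-10, atol=1e-10 * scale)
    assert np.allclose(flux.y, qy, rtol=1e-10, atol=1e-10 * scale)


def test_uniform_state_gives_zero_flux(small_grid):
    state = PhaseState.uniform(small_grid, ("fluid", "cells", "ecm"),
                               (0.25, 0.7, 0.05))
    mech = Mechanics.equal_drag([0, 500, 300], 1e5, u0_opt=0.5)
    flux = solve_fluxes(state, mech)
    assert np.all(flux.x == 0) and np.all(flux.y == 0)


def test_cells_flow_toward_wound():
    """Across the wound rim the cell flux points into the fluid-rich wound:
    components move down the excess-pressure gradient."""
    grid = Grid(8, 5, 0.01)
    u1 = np.full(grid.shape, 0.7)
    u1[:4, :] = 0.0  # wound on the left
    # squeeze the fluid slightly in the tissue so the stress is active there
    u2 = np.full(grid.shape, 0.10)
    u = np.stack([1 - u1 - u2, u1, u2])
    state = PhaseState(grid, ("fluid", "cells", "ecm"), u)
    mech = Mechanics.equal_drag([0, 500, 300], 1e5, u0_opt=0.25)
    flux = solve_fluxes(state, mech)
    # rim face between cells 3 (wound, u0 high) and 4 (tissue, u0 = 0.20)
    assert flux.x[1, 4, :].max() < 0.0  # cells move in -x, into the wound


def test_zero_net_flux_and_finite_where_vanishing(small_grid, rng):
    state = random_state(small_grid, rng, 4)
    state.u[2, 2, 2] = 0.0  # a vanished component somewhere
    state.close_fluid()
    mech = random_mechanics(rng, 4)
    flux = solve_fluxes(state, mech)
    assert flux.net_flux_max() < 1e-18 * max(1.0, np.abs(flux.x).max())
    assert np.all(np.isfinite(flux.x)) and np.all(np.isfinite(flux.y))


def test_mirror_symmetry_gives_antisymmetric_flux(rng):
    grid = Grid(7, 7, 0.05)
    half = rng.uniform(0.1, 0.5, size=(4, 7, 7))
    u_sym = 0.5 * (half + half[:, ::-1, :])  # symmetric in x
    u = u_sym / u_sym.sum(axis=0) * 0.8
    u[0] = 1 - u[1:].sum(axis=0)
    state = PhaseState(grid, ("fluid", "a", "b", "c"), u)
    mech = random_mechanics(rng, 4)
    flux = solve_fluxes(state, mech)
    assert np.allclose(flux.x, -flux.x[:, ::-1, :], atol=1e-18)
    assert np.allclose(flux.y, flux.y[:, ::-1, :], atol=1e-18)


@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 4))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_local_matrices_nonsingular(seed, ncomp):
    """Well-posedness: positive fluid fraction and strictly positive drags
    give invertible local systems at every face."""
    rng = np.random.default_rng(seed)
    grid = Grid(3, 3, 0.1)
    state = random_state(grid, rng, ncomp)
    mech = random_mechanics(rng, ncomp)
    psi = excess_pressure_all(state, mech)
    uP = state.u * psi
    for fi in range(1, grid.nx):
        for j in range(grid.ny):
            u_f = 0.5 * (state.u[:, fi, j] + state.u[:, fi - 1, j])
            grad = (uP[1:, fi, j] - uP[1:, fi - 1, j]) / grid.h
            A, _ = assemble_local_system(u_f, grad, mech.drag)
            assert np.abs(np.linalg.det(A)) > 0.0


def test_pressure_gradient_forms(small_grid, rng):
    state = PhaseState.uniform(small_grid, ("fluid", "cells"), (0.3, 0.7))
    mech = Mechanics.equal_drag([0, 400.0], 1e5, u0_opt=0.6)
    # uniform state: zero pressure gradient
    pg = pressure_gradient(state, mech)
    assert np.all(pg.x == 0) and np.all(pg.y == 0)
    # single component: equals -grad(u1 Psi1)
    state = random_state(small_grid, rng, 2)
    pg = pressure_gradient(state, mech)
    psi = excess_pressure_all(state, mech)
    g = gradient_faces(small_grid, state.u[1] * psi[1])
    assert np.allclose(pg.x, -g.x) and np.allclose(pg.y, -g.y)


def test_momentum_residual_of_solution(small_grid, rng):
    """Substituting the solved fluxes and the eliminated pressure gradient
    back into the per-component momentum balance gives zero residual."""
    state = random_state(small_grid, rng, 3)
    mech = random_mechanics(rng, 3)
    flux = solve_fluxes(state, mech)
    psi = excess_pressure_all(state, mech)
    uP = state.u * psi
    grid = state.grid
    gp = pressure_gradient(state, mech)
    scale = max(np.abs(flux.x).max() * mech.drag.max(), 1.0)
    for fi in range(1, grid.nx):
        for j in range(grid.ny):
            u_f = 0.5 * (state.u[:, fi, j] + state.u[:, fi - 1, j])
            gradP = (uP[:, fi, j] - uP[:, fi - 1, j]) / grid.h
            q = flux.x[:, fi, j]
            for i in range(state.ncomp):
                drag_i = sum(mech.drag[i, m] * (u_f[i] * q[m] - u_f[m] * q[i])
                             for m in range(state.ncomp) if m != i)
                res = -u_f[i] * gp.x[fi, j] - gradP[i] + drag_i
                assert abs(res) < 1e-10 * scale
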