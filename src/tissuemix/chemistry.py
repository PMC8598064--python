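"""Steady-state chemical transport in the interstitial fluid.

A chemical (oxygen, in all shipped scenarios) diffuses in the fluid phase
with a fluid-dependent diffusivity ``D = D_hat · u0^delta``, is advected by
the fluid flux, consumed by cells, and pinned to prescribed values on the
domain boundary and at capillary source cells.  Because chemical diffusion
is much faster than cell motion, the field is relaxed to steady state at
every mechanical step:

    −D Δo + ∇o·(u0 v0 − D_hat ∇u0^delta) + o g0 + o u0 Σ_j c_j u_j − r = 0

with Dirichlet conditions o = o_bar on the boundary ring and o = o_cap on
the capillary set.  The net fluid production g0 and the consumption rates
may themselves depend on o (tanh growth/death responses), which makes the
problem nonlinear; it is solved by Newton iteration with an analytic
Jacobian for the transport part and a per-cell finite-difference derivative
of the (purely local) reaction part.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import FaceField, Grid, faces_to_cells, gradient_faces
from .params import ChemicalParams, Kinetics, Mechanics
from .state import PhaseState

__all__ = [
    "Reaction",
    "dirichlet_values",
    "residual",
    "solve_steady_state",
    "oxygen_reaction",
    "hypoxia_histogram",
    "hypoxic_fraction",
    "NewtonError",
]

# reaction(o) -> (k, r): contribution to the residual is k*o - r, both cell
# fields; k collects g0(o) + u0 (Σ c_j(o) u_j + λ)
Reaction = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


class NewtonError(RuntimeError):
    pass


def dirichlet_values(grid: Grid, p: ChemicalParams,
                     cap_values: Optional[np.ndarray] = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mask and prescribed values of all Dirichlet-constrained cells
    (the boundary ring plus the capillary set)."""
    mask = np.zeros(grid.shape, dtype=bool)
    vals = np.zeros(grid.shape)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = True
    vals[mask] = p.o_bar
    if len(p.capillaries):
        ii, jj = p.capillaries[:, 0], p.capillaries[:, 1]
        if (np.any(ii <= 0) or np.any(ii >= grid.nx - 1)
                or np.any(jj <= 0) or np.any(jj >= grid.ny - 1)):
            raise ValueError("capillary cells must lie strictly inside the domain")
        cv = p.capillary_values() if cap_values is None else np.asarray(cap_values)
        mask[ii, jj] = True
        vals[ii, jj] = cv
    return mask, vals


def _transport_fields(grid: Grid, u0: np.ndarray, q0: FaceField, p: ChemicalParams):
    """Diffusivity D and cell-centered carrier velocity w = u0 v0 − D_hat ∇u0^δ."""
    if np.any(u0[1:-1, 1:-1] <= 0):
        raise ValueError("interior cell with vanishing interstitial fluid: "
                         "chemical diffusivity degenerates")
    D = p.D_hat * np.maximum(u0, 0.0) ** p.delta
    wx, wy = faces_to_cells(grid, q0)
    gx, gy = faces_to_cells(grid, gradient_faces(grid, np.maximum(u0, 0.0) ** p.delta))
    return D, wx - p.D_hat * gx, wy - p.D_hat * gy


def _upwind_masks(grid: Grid, D, wx, wy) -> tuple[np.ndarray, np.ndarray]:
    """Cells where the advection term switches from centered to upwind
    differencing: local cell Péclet number |w| h / (2D) above 1.

    Centered differences lose monotonicity there (steep diffusivity drops
    at low fluid fractions); the hybrid keeps second order wherever the
    problem is smooth and diffusion-dominated.
    """
    pe_x = np.abs(wx) * grid.h / (2.0 * np.maximum(D, 1e-300))
    pe_y = np.abs(wy) * grid.h / (2.0 * np.maximum(D, 1e-300))
    return pe_x > 1.0, pe_y > 1.0


def residual(grid: Grid, o: np.ndarray, u0: np.ndarray, q0: FaceField,
             p: ChemicalParams, reaction: Reaction,
             cap_values: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-cell residual of the discretized steady-state equation.

    Dirichlet cells carry ``o − prescribed``; interior cells carry the
    5-point residual of the transport-reaction balance, with the advection
    term centered (upwinded where the local Péclet number exceeds 1).
    """
    o = grid.check_cell(o, "chemical field")
    h = grid.h
    D, wx, wy = _transport_fields(grid, u0, q0, p)
    mask, vals = dirichlet_values(grid, p, cap_values)
    upx, upy = _upwind_masks(grid, D, wx, wy)

    lap = np.zeros(grid.shape)
    lap[1:-1, 1:-1] = (o[2:, 1:-1] + o[:-2, 1:-1] + o[1:-1, 2:] + o[1:-1, :-2]
                       - 4.0 * o[1:-1, 1:-1]) / h**2
    dox = np.zeros(grid.shape)
    doy = np.zeros(grid.shape)
    dox[1:-1, :] = (o[2:, :] - o[:-2, :]) / (2 * h)
    doy[:, 1:-1] = (o[:, 2:] - o[:, :-2]) / (2 * h)
    dox_up = np.zeros(grid.shape)
    doy_up = np.zeros(grid.shape)
    dox_up[1:-1, :] = np.where(wx[1:-1, :] > 0, (o[1:-1, :] - o[:-2, :]) / h,
                               (o[2:, :] - o[1:-1, :]) / h)
    doy_up[:, 1:-1] = np.where(wy[:, 1:-1] > 0, (o[:, 1:-1] - o[:, :-2]) / h,
                               (o[:, 2:] - o[:, 1:-1]) / h)
    dox = np.where(upx, dox_up, dox)
    doy = np.where(upy, doy_up, doy)
    k, r = reaction(o)
    res = -D * lap + wx * dox + wy * doy + k * o - r
    res[mask] = o[mask] - vals[mask]
    return res


def _transport_jacobian(grid: Grid, D, wx, wy, mask) -> sp.csr_matrix:
    """Sparse Jacobian of the o-linear transport part, identity on Dirichlet rows."""
    nx, ny = grid.shape
    h = grid.h
    N = nx * ny
    upx, upy = _upwind_masks(grid, D, wx, wy)

    def lin(i, j):
        return i * ny + j

    I, J, V = [], [], []
    free = ~mask
    ii, jj = np.nonzero(free)
    c = lin(ii, jj)
    w_x, w_y = wx[ii, jj], wy[ii, jj]
    ux, uy = upx[ii, jj], upy[ii, jj]
    # center: diffusion plus the upwinded advection contributions
    center = 4.0 * D[ii, jj] / h**2
    center = center + np.where(ux, np.abs(w_x) / h, 0.0)
    center = center + np.where(uy, np.abs(w_y) / h, 0.0)
    I.append(c); J.append(c); V.append(center)
    # east/west/north/south neighbours
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = lin(ii + di, jj + dj)
        coef = -D[ii, jj] / h**2
        if di != 0:
            centered = di * w_x / (2 * h)
            upwind = np.where(np.sign(w_x) == -di, -np.abs(w_x) / h, 0.0)
            coef = coef + np.where(ux, upwind, centered)
        else:
            centered = dj * w_y / (2 * h)
            upwind = np.where(np.sign(w_y) == -dj, -np.abs(w_y) / h, 0.0)
            coef = coef + np.where(uy, upwind, centered)
        I.append(c); J.append(nb); V.append(np.broadcast_to(coef, c.shape))
    # Dirichlet rows: identity
    di_, dj_ = np.nonzero(mask)
    d = lin(di_, dj_)
    I.append(d); J.append(d); V.append(np.ones(len(d)))
    I = np.concatenate(I); J = np.concatenate(J); V = np.concatenate(V)
    return sp.csr_matrix((V, (I, J)), shape=(N, N))


def solve_steady_state(state: PhaseState, q0: FaceField, p: ChemicalParams,
                       reaction: Reaction, tol: Optional[float] = None,
                       max_iter: int = 50,
                       cap_values: Optional[np.ndarray] = None,
                       initial: Optional[np.ndarray] = None
                       ) -> tuple[np.ndarray, int]:
    """Newton iteration on the steady-state residual.

    Returns the solved field and the iteration count.  The reaction part is
    local in o, so its Jacobian contribution is diagonal and evaluated by a
    centered finite difference of ``k(o)·o − r(o)`` per cell.
    """
    grid = state.grid
    u0 = state.u[0]
    mask, vals = dirichlet_values(grid, p, cap_values)
    scale = max(float(p.o_bar), float(np.max(np.asarray(p.o_cap))) if np.size(p.o_cap) else 0.0)
    if tol is None:
        tol = 1e-9 * max(scale, 1.0)
    o = np.full(grid.shape, float(p.o_bar)) if initial is None else initial.copy()
    o[mask] = vals[mask]

    D, wx, wy = _transport_fields(grid, u0, q0, p)
    L = _transport_jacobian(grid, D, wx, wy, mask)
    # residual entries scale like |L|·o; don't demand convergence below the
    # round-off floor of that scale
    tol = max(tol, np.abs(L).max() * max(scale, 1.0) * 1e-14)
    N = grid.nx * grid.ny
    eps = 1e-6 * max(scale, 1.0)

    fnorm = None
    for it in range(1, max_iter + 1):
        F = residual(grid, o, u0, q0, p, reaction, cap_values)
        fnorm = np.abs(F).max()
        if fnorm < tol:
            if np.any(o < -tol):
                import warnings
                warnings.warn("steady-state chemical field has negative values")
            return o, it - 1
        # diagonal derivative of the local reaction term
        kp, rp = reaction(o + eps)
        km, rm = reaction(o - eps)
        dreac = ((kp * (o + eps) - rp) - (km * (o - eps) - rm)) / (2 * eps)
        dreac[mask] = 0.0
        J = L + sp.diags(dreac.ravel(), 0, shape=(N, N), format="csr")
        delta = spla.spsolve(J.tocsc(), F.ravel()).reshape(grid.shape)
        # backtracking: accept the largest step in {1, 1/2, ...} that does
        # not increase the residual norm (full steps once near the root)
        lam = 1.0
        for _ in range(12):
            trial = o - lam * delta
            fn = np.abs(residual(grid, trial, u0, q0, p, reaction, cap_values)).max()
            if fn < fnorm:
                break
            lam *= 0.5
        o = o - lam * delta
    F = residual(grid, o, u0, q0, p, reaction, cap_values)
    raise NewtonError(
        f"chemical steady state: no convergence after {max_iter} iterations "
        f"(residual {np.abs(F).max():.3e}, tol {tol:.3e})")


def oxygen_reaction(state: PhaseState, kin: Kinetics, mech: Mechanics,
                    include_g0: bool = True,
                    rate_law=None) -> Reaction:
    """Reaction closure for oxygen under the oxygen-coupled healing laws.

    Consumption by live cells is ``o u0 (ℓ1 + ℓ2 b1(o)) u1`` — a base
    metabolic rate plus an extra cost of division — and the fluid production
    g0(o) feeds back into the balance (full coupling; pass
    ``include_g0=False`` for the lagged variant).
    """
    from .constitutive import rates_oxygen_coupled

    if rate_law is None:
        rate_law = rates_oxygen_coupled
    u0 = state.u[0]
    u1 = state.u[1]
    from .constitutive import _wound_trigger

    trig = _wound_trigger(state, mech)

    def reaction(o: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b1 = 0.5 * kin.b1_max * u0 * trig * (1.0 + np.tanh(kin.R2 * (o - kin.T2)))
        c1 = kin.ell1 + kin.ell2 * b1
        k = u0 * (c1 * u1 + 0.0)
        if include_g0:
            g = rate_law(state, kin, mech, {"oxygen": o})
            k = k + g[0]
        return k, np.zeros_like(o)

    return reaction


def hypoxia_histogram(o: np.ndarray, bins=20, range_=None):
    """Histogram of the oxygen partial pressure over all cells."""
    return np.histogram(np.asarray(o).ravel(), bins=bins, range=range_)


def hypoxic_fraction(o: np.ndarray, threshold: float = 10.0) -> float:
    """Share of cells below the hypoxic PO2 threshold (mmHg)."""
    o = np.asarray(o)
    return float(np.count_nonzero(o < threshold)) / o.size
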