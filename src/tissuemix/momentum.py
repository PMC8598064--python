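"""Momentum-balance closure: solve for the advective fluxes q_i = u_i v_i.

The flux — not the velocity — is the state variable, so the local linear
systems stay well-posed where a component's volume fraction vanishes.
Because the excess pressures Ψ_i are velocity-independent scalars, the
momentum balance couples components only pointwise: at every face and for
each spatial direction separately we solve a dense (ncomp−1)×(ncomp−1)
system for the non-fluid fluxes and recover the fluid flux from the
zero-net-flux condition q_0 = −Σ_{j≥1} q_j.

Row i of the local system (i, j over non-fluid components):

    A_ii = α̂_i0 u_i + Σ_{j≠i} α̂_ij u_j        (sum over all components)
    A_ij = u_i (α̂_i0 − α̂_ij)                   (j ≥ 1, j ≠ i)
    r_i  = u_i G(Σ_j u_j Ψ_j) − G(u_i Ψ_i)

with u evaluated at the face by averaging and G the face-normal gradient of
the cell-centered products u_i Ψ_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import excess_pressure_all
from .grid import FaceField, Grid, gradient_faces
from .params import Mechanics
from .state import PhaseState

__all__ = ["FluxSolution", "assemble_local_system", "solve_fluxes",
           "pressure_gradient", "velocity_diagnostic"]

# relative Tikhonov floor for faces where every structural fraction vanishes
_EPS_REL = 1e-12


@dataclass
class FluxSolution:
    """Per-component face fluxes; index 0 is the interstitial fluid."""

    grid: Grid
    names: tuple[str, ...]
    x: np.ndarray  # (ncomp, nx+1, ny)
    y: np.ndarray  # (ncomp, nx, ny+1)

    def component(self, i: int) -> FaceField:
        return FaceField(self.x[i], self.y[i])

    def net_flux_max(self) -> float:
        """max over faces of |Σ_i q_i| — zero up to round-off by construction."""
        return max(np.abs(self.x.sum(axis=0)).max(), np.abs(self.y.sum(axis=0)).max())

def velocity_diagnostic(state: PhaseState, flux: FluxSolution, i: int,
                        u_face_min: float = 1e-8) -> FaceField:
    """Diagnostic velocity v_i = q_i / u_i, NaN-masked where u_i ~ 0."""
    from .grid import face_average

    uf = face_average(state.grid, state.u[i])
    vx = np.where(uf.x >= u_face_min, flux.x[i] / np.maximum(uf.x, u_face_min), np.nan)
    vy = np.where(uf.y >= u_face_min, flux.y[i] / np.maximum(uf.y, u_face_min), np.nan)
    return FaceField(vx, vy)


def assemble_local_system(u_face: np.ndarray, grad_uP: np.ndarray,
                          drag: np.ndarray, rhs_sign: int = 1
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Local momentum system at a single face.

    Parameters
    ----------
    u_face : (ncomp,) volume fractions averaged to the face (fluid first).
    grad_uP : (ncomp-1,) face-normal gradient of u_i Ψ_i per non-fluid
        component.
    drag : (ncomp, ncomp) symmetric α̂ matrix (diagonal ignored).

    Returns the dense matrix A and right-hand side r of size ncomp−1.
    """
    u_face = np.asarray(u_face, dtype=float)
    grad_uP = np.asarray(grad_uP, dtype=float)
    ncomp = len(u_face)
    n = ncomp - 1
    if np.any(u_face < -1e-12) or u_face.sum() > 1 + 1e-6:
        raise ValueError("face volume fractions invalid")
    off = drag[~np.eye(ncomp, dtype=bool)]
    if np.any(off <= 0):
        raise ValueError("nonpositive drag coefficient")
    A = np.empty((n, n))
    for a in range(n):
        i = a + 1
        for b in range(n):
            j = b + 1
            if i == j:
                s = sum(drag[i, jj] * u_face[jj] for jj in range(ncomp) if jj != i)
                A[a, b] = drag[i, 0] * u_face[i] + s
            else:
                A[a, b] = u_face[i] * (drag[i, 0] - drag[i, j])
    GS = grad_uP.sum()
    r = rhs_sign * (u_face[1:] * GS - grad_uP)
    return A, r


def _batched_systems(u_f: np.ndarray, grad_uP: np.ndarray, drag: np.ndarray,
                     rhs_sign: int) -> np.ndarray:
    """Vectorized assembly and solve over all faces of one direction.

    u_f : (ncomp, F) face-averaged fractions; grad_uP : (n, F) gradients of
    u_iΨ_i. Returns q : (n, F).
    """
    ncomp, F = u_f.shape
    n = ncomp - 1
    dr = drag.copy()
    np.fill_diagonal(dr, 0.0)
    # off-diagonal pattern u_i (α̂_i0 − α̂_ij); the diagonal is overwritten
    A = u_f[1:, None, :] * (dr[1:, 0][:, None, None] - dr[1:, 1:][:, :, None])
    T = dr[1:, :] @ u_f  # Σ_{j≠i} α̂_ij u_j   (diagonal of dr is zero)
    diag = dr[1:, 0][:, None] * u_f[1:] + T
    idx = np.arange(n)
    A[idx, idx, :] = diag
    A = np.moveaxis(A, -1, 0)  # (F, n, n)
    GS = grad_uP.sum(axis=0)
    r = rhs_sign * (u_f[1:] * GS[None, :] - grad_uP)  # (n, F)
    r = r.T  # (F, n)
    # regularize only degenerate faces (all structural fractions vanish, so
    # A -> 0); regular faces are solved exactly
    scale = np.abs(A).max(axis=(1, 2))
    drag_scale = np.abs(dr).max()
    degenerate = scale < 1e-10 * drag_scale
    if np.any(degenerate):
        A[degenerate, idx[:, None], idx[None, :]] = np.where(
            np.eye(n, dtype=bool), _EPS_REL * drag_scale, 0.0)
        r[degenerate] = 0.0
    q = np.linalg.solve(A, r[..., None])[..., 0]  # (F, n)
    return q.T


def solve_fluxes(state: PhaseState, mech: Mechanics, rhs_sign: int = 1) -> FluxSolution:
    """Solve the momentum closure for all component fluxes on every face.

    Boundary faces carry zero flux (sealed tissue sample); the interstitial
    fluid flux is recovered from q_0 = −Σ_{j≥1} q_j, so the net flux
    vanishes identically at every face.
    """
    grid = state.grid
    ncomp = state.ncomp
    psi = excess_pressure_all(state, mech)
    uP = state.u * psi  # (ncomp, nx, ny); row 0 is zero
    h = grid.h

    qx = np.zeros((ncomp, grid.nx + 1, grid.ny))
    qy = np.zeros((ncomp, grid.nx, grid.ny + 1))

    # x-direction interior faces
    u_fx = 0.5 * (state.u[:, 1:, :] + state.u[:, :-1, :])
    g_uPx = (uP[1:, 1:, :] - uP[1:, :-1, :]) / h
    shape = u_fx.shape[1:]
    q = _batched_systems(u_fx.reshape(ncomp, -1),
                         g_uPx.reshape(ncomp - 1, -1), mech.drag, rhs_sign)
    qx[1:, 1:-1, :] = q.reshape((ncomp - 1,) + shape)

    # y-direction interior faces
    u_fy = 0.5 * (state.u[:, :, 1:] + state.u[:, :, :-1])
    g_uPy = (uP[1:, :, 1:] - uP[1:, :, :-1]) / h
    shape = u_fy.shape[1:]
    q = _batched_systems(u_fy.reshape(ncomp, -1),
                         g_uPy.reshape(ncomp - 1, -1), mech.drag, rhs_sign)
    qy[1:, :, 1:-1] = q.reshape((ncomp - 1,) + shape)

    qx[0] = -qx[1:].sum(axis=0)
    qy[0] = -qy[1:].sum(axis=0)
    return FluxSolution(grid, state.names, qx, qy)


def pressure_gradient(state: PhaseState, mech: Mechanics) -> FaceField:
    """Interphase-pressure gradient ∇p = −∇ Σ_j u_j Ψ_j (diagnostic)."""
    psi = excess_pressure_all(state, mech)
    S = (state.u * psi).sum(axis=0)
    return -1.0 * gradient_faces(state.grid, S)
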