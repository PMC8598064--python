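"""Time integration: Heun predictor-corrector with no-voids closure.

Each step advances the structural components i = 1..n+1 by the balance
``du_i/dt = g_i − ∇·q_i`` and recovers the fluid fraction from the no-voids
condition, so Σ_i u_i = 1 holds exactly after every step.  The corrector is
the trapezoidal two-stage Runge-Kutta: fluxes (and, when a chemical field
is coupled, the steady-state chemical solve and the rates) are evaluated at
the current state and again at the Euler-predicted state, and the two
tendencies are averaged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .chemistry import oxygen_reaction, solve_steady_state
from .constitutive import RATE_REGISTRY
from .grid import divergence_cells
from .momentum import solve_fluxes
from .scenarios import ScenarioConfig, build_initial, metrics
from .state import PhaseState

__all__ = ["stable_dt", "stability_report", "enforce_bounds", "step", "run",
           "Trajectory"]


def stable_dt(b_cell: float, b_ecm: float, u0_opt: float, u_ecm_opt: float,
              k_sum: float, alpha_hat: float, h: float,
              drag_divide: bool = True) -> float:
    """Worst-case time-step bound

        Δt ≤ 1 / ( b_cell (1 − u0_opt)/h + b_ecm u_ecm_opt
                   + 4 A (k_sum) u0_opt / h² )

    where ``k_sum`` is the summed strain-stress coefficient of the mobile
    components and ``A`` the drag factor: 1/α̂ when ``drag_divide`` (fluxes
    scale as k/α̂), α̂ otherwise.  Returns +inf when unconstrained.
    """
    A = 1.0 / alpha_hat if drag_divide else alpha_hat
    denom = (b_cell * (1.0 - u0_opt) / h + b_ecm * u_ecm_opt
             + 4.0 * A * k_sum * u0_opt / h**2)
    if denom == 0.0:
        return math.inf
    return 1.0 / denom


def stability_report(cfg: ScenarioConfig) -> dict:
    """Evaluate the bound under both drag interpretations for a config."""
    kin, mech, grid = cfg.kin, cfg.mech, cfg.grid
    b_cell = max(kin.b1_max, kin.b2_hat)
    b_ecm = max(kin.b2_max, kin.b3_max, kin.b3_hat)
    u_ecm_opt = float(np.max(np.asarray(kin.u_ecm_opt)))
    u0_opt = float(np.max(np.asarray(mech.u0_opt)))
    k_sum = float(mech.k[1:].sum())
    off = mech.drag[~np.eye(len(mech.k), dtype=bool)]
    alpha = float(off.max())
    out = {}
    for divide in (True, False):
        out["divide" if divide else "literal"] = stable_dt(
            b_cell, b_ecm, u0_opt, u_ecm_opt, k_sum, alpha, grid.h, divide)
    out["dt"] = cfg.num.dt
    out["satisfied"] = cfg.num.dt <= out["divide" if cfg.num.drag_divide else "literal"]
    return out


def enforce_bounds(state: PhaseState, beta: float) -> dict:
    """Limiter: clamp negative fractions to 0 and cap the total non-fluid
    fraction at β (proportional rescale), then re-close the fluid.

    Returns diagnostics: total clamped mass and number of capped cells.
    """
    u = state.u
    neg = np.minimum(u[1:], 0.0)
    clamped = float(-neg.sum())
    np.maximum(u[1:], 0.0, out=u[1:])
    s = u[1:].sum(axis=0)
    over = s > beta
    ncapped = int(np.count_nonzero(over))
    if ncapped:
        scale = np.where(over, beta / np.maximum(s, beta), 1.0)
        u[1:] *= scale
    state.close_fluid()
    return {"clamped_mass": clamped, "capped_cells": ncapped}


def _stage(state: PhaseState, cfg: ScenarioConfig,
           o_prev: Optional[np.ndarray], solve_chem: bool):
    """One tendency evaluation: fluxes, chemical steady state, rates."""
    rate_law = RATE_REGISTRY[cfg.rate_law]
    flux = solve_fluxes(state, cfg.mech, rhs_sign=cfg.num.rhs_sign)
    chem_fields = dict(state.chem)
    iters = 0
    if cfg.chem is not None:
        if solve_chem or "oxygen" not in chem_fields:
            reaction = oxygen_reaction(state, cfg.kin, cfg.mech)
            o, iters = solve_steady_state(
                state, flux.component(0), cfg.chem, reaction,
                tol=cfg.num.newton_tol * max(cfg.chem.o_bar, 1.0),
                max_iter=cfg.num.newton_max_iter, initial=o_prev)
            chem_fields["oxygen"] = o
    g = rate_law(state, cfg.kin, cfg.mech, chem_fields)
    du = np.empty_like(state.u[1:])
    for i in range(1, state.ncomp):
        du[i - 1] = g[i] - divergence_cells(state.grid, flux.component(i))
    return du, chem_fields, iters


def step(state: PhaseState, cfg: ScenarioConfig) -> tuple[PhaseState, dict]:
    """Advance one Δt with the Heun predictor-corrector."""
    dt = cfg.num.dt
    o_prev = state.chem.get("oxygen")
    du1, chem1, it1 = _stage(state, cfg, o_prev, solve_chem=True)

    pred = state.copy()
    pred.u[1:] += dt * du1
    pred.close_fluid()
    enforce_bounds(pred, cfg.num.beta)
    pred.chem = chem1

    du2, chem2, it2 = _stage(pred, cfg, chem1.get("oxygen"),
                             solve_chem=cfg.num.chem_every_stage)

    new = state.copy()
    new.u[1:] = state.u[1:] + 0.5 * dt * (du1 + du2)
    new.close_fluid()
    diag = enforce_bounds(new, cfg.num.beta)
    new.chem = chem2
    diag["newton_iters"] = it1 + it2
    if diag["clamped_mass"] > 1e-6:
        warnings.warn(f"limiter clamped {diag['clamped_mass']:.2e} of volume "
                      "fraction mass in one step")
    if not np.all(np.isfinite(new.u)):
        raise FloatingPointError("non-finite volume fractions after step")
    return new, diag


@dataclass
class Trajectory:
    cfg: ScenarioConfig
    metrics: pd.DataFrame
    snapshots: dict[int, np.ndarray]
    final_state: PhaseState
    ref_totals: np.ndarray
    seed: int

    def tumor_mass(self) -> np.ndarray:
        return self.metrics["tumor_mass"].to_numpy()


def run(cfg: ScenarioConfig, seed: Optional[int] = None,
        n_steps: Optional[int] = None,
        record_snapshots: bool = True) -> Trajectory:
    """Initialize a scenario and integrate it for the configured number of
    steps, recording metrics each step and snapshots at the configured
    cadence (plus initial and final).  Deterministic given the seed."""
    if seed is None:
        seed = cfg.num.seed
    if n_steps is None:
        n_steps = cfg.num.n_steps
    rng = np.random.default_rng(seed)
    state, ref = build_initial(cfg, rng)

    report = stability_report(cfg)
    if not report["satisfied"]:
        warnings.warn(
            f"time step dt={report['dt']} exceeds the worst-case stability "
            f"bound {report['divide']:.3g} (divide interpretation; literal: "
            f"{report['literal']:.3g})")

    rows = []
    snaps: dict[int, np.ndarray] = {}
    cadence = cfg.num.snapshot_every

    def record(istep: int, st: PhaseState, diag: dict) -> None:
        row = {"step": istep, "time": istep * cfg.num.dt}
        row.update(metrics(st, ref))
        row.update({k: diag.get(k, 0) for k in
                    ("clamped_mass", "capped_cells", "newton_iters")})
        if "oxygen" in st.chem:
            row["min_oxygen"] = float(st.chem["oxygen"].min())
        rows.append(row)
        if record_snapshots and (istep in (0, n_steps)
                                 or (cadence and istep % cadence == 0)):
            snaps[istep] = st.u.copy()

    record(0, state, {})
    for istep in range(1, n_steps + 1):
        try:
            state, diag = step(state, cfg)
        except Exception as exc:
            err = RuntimeError(
                f"solver failure at step {istep} (t={istep * cfg.num.dt}); "
                f"{len(rows)} completed steps recorded")
            err.partial = Trajectory(cfg, pd.DataFrame(rows), snaps, state,
                                     ref, seed)
            raise err from exc
        record(istep, state, diag)
    return Trajectory(cfg, pd.DataFrame(rows), snaps, state, ref, seed)
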