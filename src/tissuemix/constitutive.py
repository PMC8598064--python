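"""Excess-pressure stresses and scenario net-production (growth/decay) laws.

Every rate law returns the full set ``g_i`` with the fluid rate defined as
``g_0 = -Σ_{i≥1} g_i``, so no net volume is ever created or destroyed.

The stress a structural component feels is the scalar excess pressure

    Ψ_i = k_i (u0_opt − u0)+ ,      Ψ_0 ≡ 0,

i.e. tissue is under stress exactly where the interstitial-fluid fraction
has been squeezed below its optimum.
"""

from __future__ import annotations

from typing import Callable, Dict, Mapping

import numpy as np

from .grid import grad_norm_sq
from .params import Kinetics, Mechanics, positive_part
from .state import PhaseState

__all__ = [
    "excess_pressure",
    "excess_pressure_all",
    "close_rates",
    "rates_regeneration",
    "rates_oxygen_coupled",
    "rates_tumor",
    "RATE_REGISTRY",
    "RateLaw",
]

RateLaw = Callable[[PhaseState, Kinetics, Mechanics, Mapping[str, np.ndarray]], np.ndarray]


def excess_pressure(u0: np.ndarray, k_i: float, u0_opt) -> np.ndarray:
    """Scalar excess pressure Ψ_i = k_i (u0_opt − u0)+ of one component."""
    if np.any(np.asarray(k_i) < 0):
        raise ValueError("strain-stress coefficient must be >= 0")
    return k_i * positive_part(u0_opt - np.asarray(u0, dtype=float))


def excess_pressure_all(state: PhaseState, mech: Mechanics) -> np.ndarray:
    """Ψ_i for every component, shape (ncomp, nx, ny); Ψ_0 ≡ 0."""
    psi = np.zeros_like(state.u)
    dev = positive_part(mech.u0_opt - state.u[0])
    for i in range(1, state.ncomp):
        psi[i] = mech.k[i] * dev
    return psi


def close_rates(state: PhaseState, g_nonfluid: np.ndarray) -> np.ndarray:
    """Assemble the full rate set with g_0 = −Σ g_i (zero net volume change)."""
    g = np.empty_like(state.u)
    g[1:] = g_nonfluid
    g[0] = -g_nonfluid.sum(axis=0)
    return g


def _wound_trigger(state: PhaseState, mech: Mechanics) -> np.ndarray:
    """‖∇[(u0 − u0_opt)+]‖₂, the scalar gradient trigger for regrowth.

    The Euclidean norm of the gradient of the excess-fluid deviation: it is
    non-zero only where that deviation varies in space — the rim of a wound
    — which restricts division to where tissue is irregular.  (The norm, not
    its square: the worst-case growth rate is then b_max(1 − u0_opt)/h,
    the form that enters the time-step stability bound.)
    """
    dev = positive_part(state.u[0] - mech.u0_opt)
    return np.sqrt(grad_norm_sq(state.grid, dev))


def rates_regeneration(state: PhaseState, kin: Kinetics, mech: Mechanics,
                       chem: Mapping[str, np.ndarray] = {}) -> np.ndarray:
    """Three-component wound healing: (fluid, cells, ecm).

    Cells divide where the wound trigger is active and fluid is available;
    the ECM is secreted by cells wherever it sits below its optimum.
    """
    if state.ncomp != 3:
        raise ValueError("regeneration law expects components (fluid, cells, ecm)")
    u0, u1, u2 = state.u
    b1 = kin.b1_max * u0 * _wound_trigger(state, mech)
    g1 = b1 * u1
    b2 = kin.b2_max * u0 * u1 * positive_part(kin.u_ecm_opt - u2)
    g2 = b2
    return close_rates(state, np.stack([g1, g2]))


def rates_oxygen_coupled(state: PhaseState, kin: Kinetics, mech: Mechanics,
                         chem: Mapping[str, np.ndarray] = {}) -> np.ndarray:
    """Four-component vascularized healing: (fluid, live, dead, ecm).

    Live-cell growth saturates with oxygen through ``1 + tanh(R2(o − T2))``
    and death rises as oxygen falls through ``1 − tanh(R1(o − T1))``; dying
    cells join the dead pool, which disintegrates back into fluid at the
    constant rate d2.
    """
    if state.ncomp != 4:
        raise ValueError("oxygen-coupled law expects (fluid, live, dead, ecm)")
    if "oxygen" not in chem:
        raise ValueError("oxygen-coupled rate law requires a solved 'oxygen' field")
    o = chem["oxygen"]
    u0, u1, u2, u3 = state.u
    u0_opt = mech.u0_opt
    b1 = (0.5 * kin.b1_max * u0 * _wound_trigger(state, mech)
          * (1.0 + np.tanh(kin.R2 * (o - kin.T2))))
    d1 = (kin.d1_hat * positive_part(u0_opt - u0) / u0_opt
          + 0.5 * kin.d1_tilde * (1.0 - np.tanh(kin.R1 * (o - kin.T1))))
    g1 = (b1 - d1) * u1
    g2 = d1 * u1 - kin.d2 * u2
    g3 = kin.b3_max * u0 * u1 * positive_part(kin.u_ecm_opt - u3)
    return close_rates(state, np.stack([g1, g2, g3]))


def oxygen_death_rate(o, kin: Kinetics, u0, u0_opt) -> np.ndarray:
    """The live-cell decay response d1(o) on its own (plotting/diagnostics)."""
    return (kin.d1_hat * positive_part(u0_opt - u0) / u0_opt
            + 0.5 * kin.d1_tilde * (1.0 - np.tanh(kin.R1 * (np.asarray(o) - kin.T1))))


def rates_tumor(state: PhaseState, kin: Kinetics, mech: Mechanics,
                chem: Mapping[str, np.ndarray] = {}) -> np.ndarray:
    """Four-component tumor/ECM interaction: (fluid, normal, tumor, ecm).

    Normal cells only die (fluid starvation); tumor cells proliferate with
    available fluid and die when it is squeezed out; the ECM is rebuilt by
    normal cells up to a target that the presence of tumor inflates by the
    active-response factor ``1 + α u2``.
    """
    if state.ncomp != 4:
        raise ValueError("tumor law expects (fluid, normal, tumor, ecm)")
    if np.any(state.u < -1e-12):
        raise ValueError("negative volume fractions")
    u0, u1, u2, u3 = state.u
    dev = positive_part(mech.u0_opt - u0)
    g1 = -kin.d1_hat * u1 * dev
    g2 = (kin.b2_hat * u0 - kin.d2_hat * dev) * u2
    target = (1.0 + kin.alpha * u2) * kin.u_ecm_opt
    g3 = kin.b3_hat * u0 * u1 * positive_part(target - u3)
    return close_rates(state, np.stack([g1, g2, g3]))


RATE_REGISTRY: Dict[str, RateLaw] = {
    "regeneration": rates_regeneration,
    "oxygen_coupled": rates_oxygen_coupled,
    "tumor": rates_tumor,
}
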