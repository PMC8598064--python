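"""Scenario configurations, initial-condition generators and summary metrics.

Shipped example families
------------------------
* ``1a``–``1d``  three-component wound healing (fluid, cells, ecm) on a
  0.3 mm square: an irregular wound is cut into a uniform cell field and
  the rim regrows it; 1c/1d additionally damage the ECM inside the wound.
* ``2`` / ``2h`` four-component vascularized healing (fluid, live, dead,
  ecm) with a capillary network and a steady-state oxygen field; ``2h``
  removes the capillaries nearest the wound, creating a hypoxic region.
* ``3a``–``3d``  tumor/ECM interaction (fluid, normal, tumor, ecm) on a
  0.41 mm square seeded with a central tumor cell; passive (k3) and active
  (b3_hat, alpha) ECM responses; ``3d`` uses a heterogeneous initial ECM.
* ``4``          the calibration setup: the tumor model with all non-tumor
  kinetics switched off, used for least-squares fitting to growth data.

The wound geometry and the capillary coordinates are generated by seeded
routines (the shapes themselves are irregular by design); user-supplied
index lists are accepted everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .grid import Grid
from .params import ChemicalParams, Kinetics, Mechanics, Numerics
from .state import PhaseState

__all__ = [
    "ScenarioConfig",
    "wound_mask",
    "place_capillaries",
    "remove_capillaries_near",
    "init_regeneration",
    "init_tumor",
    "init_heterogeneous_ecm",
    "build_initial",
    "metrics",
    "center_slice",
    "example_config",
    "list_examples",
]


@dataclass
class ScenarioConfig:
    name: str
    grid: Grid
    names: tuple[str, ...]
    rate_law: str
    mech: Mechanics
    kin: Kinetics
    num: Numerics
    chem: Optional[ChemicalParams] = None
    init: dict = field(default_factory=dict)
    source: Optional[dict] = None  # config-file echo for manifests

    def __post_init__(self) -> None:
        if len(self.mech.k) != len(self.names):
            raise ValueError("one strain-stress coefficient per component required")


# ---------------------------------------------------------------------------
# geometry generators


def wound_mask(grid: Grid, rng: np.random.Generator, n_cells: int,
               margin: int = 2) -> np.ndarray:
    """Irregular wound: a seeded random-walk blob of ``n_cells`` cells.

    The walk starts at the domain center and stays ``margin`` cells away
    from the boundary, producing a connected, irregular region.
    """
    nx, ny = grid.shape
    if n_cells >= (nx - 2 * margin) * (ny - 2 * margin):
        raise ValueError("wound larger than the interior of the domain")
    i, j = nx // 2, ny // 2
    cells = {(i, j)}
    moves = np.array([(1, 0), (-1, 0), (0, 1), (0, -1)])
    while len(cells) < n_cells:
        di, dj = moves[rng.integers(4)]
        i2, j2 = i + di, j + dj
        if margin <= i2 < nx - margin and margin <= j2 < ny - margin:
            i, j = i2, j2
            cells.add((i, j))
    mask = np.zeros(grid.shape, dtype=bool)
    for (a, b) in cells:
        mask[a, b] = True
    return mask


def place_capillaries(grid: Grid, rng: np.random.Generator, n: int,
                      margin: int = 3) -> np.ndarray:
    """Seeded uniform placement of ``n`` capillary cells in the interior."""
    nx, ny = grid.shape
    ii = np.arange(margin, nx - margin)
    jj = np.arange(margin, ny - margin)
    all_cells = np.stack(np.meshgrid(ii, jj, indexing="ij"), axis=-1).reshape(-1, 2)
    sel = rng.choice(len(all_cells), size=n, replace=False)
    return all_cells[np.sort(sel)]


def remove_capillaries_near(capillaries: np.ndarray, center: tuple[float, float],
                            radius_cells: float) -> np.ndarray:
    """Drop capillaries within ``radius_cells`` of a (i, j) center — the
    damaged-vasculature variant."""
    capillaries = np.asarray(capillaries)
    d = np.hypot(capillaries[:, 0] - center[0], capillaries[:, 1] - center[1])
    return capillaries[d > radius_cells]


# ---------------------------------------------------------------------------
# initial conditions


def init_regeneration(cfg: ScenarioConfig, rng: np.random.Generator
                      ) -> tuple[PhaseState, np.ndarray]:
    """Wounded tissue: cells at 0.7 outside the wound set B, 0 inside; ECM
    at its 0.05 optimum (optionally damaged in B); the vascular variant
    fills the wound with dead cells at 0.7.

    Returns the state and the pre-wound reference totals used to normalize
    the healing metrics.
    """
    grid = cfg.grid
    opts = cfg.init
    wound = opts.get("wound")
    if wound is None:
        frac = opts.get("wound_frac", 0.10)
        wound = wound_mask(grid, rng, max(1, int(round(frac * grid.nx * grid.ny))))
    else:
        wound = np.asarray(wound, dtype=bool)
    ncomp = len(cfg.names)
    u = np.zeros((ncomp,) + grid.shape)
    live = 1
    ecm = ncomp - 1
    u[live] = np.where(wound, 0.0, 0.7)
    u[ecm] = np.where(wound & bool(opts.get("ecm_damage", False)), 0.0, 0.05)
    if opts.get("fill_dead", False):
        if ncomp != 4:
            raise ValueError("fill_dead requires a dead-cell component")
        u[2] = np.where(wound, 0.7, 0.0)
    u[0] = 1.0 - u[1:].sum(axis=0)
    state = PhaseState(grid, cfg.names, u)
    state.validate()
    ref = np.zeros(ncomp)
    ref[live] = 0.7 * grid.nx * grid.ny
    ref[ecm] = 0.05 * grid.nx * grid.ny
    state.wound = wound  # kept for diagnostics / capillary damage placement

    # vascularized variants: place capillaries (seeded), optionally damaging
    # those nearest the wound to create the hypoxic configuration
    if cfg.chem is not None and len(cfg.chem.capillaries) == 0:
        caps = place_capillaries(grid, rng, int(opts.get("n_capillaries", 20)))
        if opts.get("hypoxic", False):
            wi, wj = np.nonzero(wound)
            centroid = (wi.mean(), wj.mean())
            caps = remove_capillaries_near(
                caps, centroid, float(opts.get("capillary_clear_radius", 8.0)))
        cfg.chem.capillaries = caps
    return state, ref


def init_heterogeneous_ecm(grid: Grid, rng: np.random.Generator, zeta: float,
                           noise_amp: float = 0.0012) -> np.ndarray:
    """Non-homogeneous ECM field

        u3(x, y) = (ζ/40)(sin 100x + sin 100y) + 0.1 + r(x, y)

    with r uniform on [−noise_amp, noise_amp] and the boundary ring fixed
    at 0.1 (x, y in mm).
    """
    X, Y = grid.cell_centers()
    u3 = zeta / 40.0 * (np.sin(100.0 * X) + np.sin(100.0 * Y)) + 0.1
    u3 = u3 + rng.uniform(-noise_amp, noise_amp, size=grid.shape)
    u3[0, :] = u3[-1, :] = 0.1
    u3[:, 0] = u3[:, -1] = 0.1
    return u3


def init_tumor(cfg: ScenarioConfig, rng: np.random.Generator
               ) -> tuple[PhaseState, np.ndarray]:
    """Central tumor seed at volume fraction 0.7, normal cells at 0.7 in the
    rest of the domain, ECM at 0.05 (or the heterogeneous field for the
    non-homogeneous variant, which also pins the optimal fluid/ECM fields
    to the initial state)."""
    grid = cfg.grid
    opts = cfg.init
    ncomp = len(cfg.names)
    if ncomp != 4:
        raise ValueError("tumor scenario expects (fluid, normal, tumor, ecm)")
    size = int(opts.get("seed_size", 1))
    if size < 1 or size > min(grid.nx, grid.ny) - 2:
        raise ValueError("tumor seed footprint outside the domain")
    i0 = (grid.nx - size) // 2
    j0 = (grid.ny - size) // 2
    seed = np.zeros(grid.shape, dtype=bool)
    seed[i0:i0 + size, j0:j0 + size] = True

    u = np.zeros((ncomp,) + grid.shape)
    u[2] = np.where(seed, 0.7, 0.0)
    u[1] = np.where(seed, 0.0, 0.7)
    if opts.get("hetero", False):
        u[3] = init_heterogeneous_ecm(grid, rng, float(opts.get("zeta", 0.5)),
                                      float(opts.get("noise_amp", 0.0012)))
        u[0] = 1.0 - u[1:].sum(axis=0)
        # normal tissue architecture: the optimal fields equal the t=0 state
        cfg.mech.u0_opt = u[0].copy()
        cfg.kin.u_ecm_opt = u[3].copy()
    else:
        u[3] = 0.05
        u[0] = 1.0 - u[1:].sum(axis=0)
    state = PhaseState(grid, cfg.names, u)
    state.validate()
    return state, state.totals()


def build_initial(cfg: ScenarioConfig, rng: np.random.Generator
                  ) -> tuple[PhaseState, np.ndarray]:
    kind = cfg.init.get("kind")
    if kind == "regeneration":
        return init_regeneration(cfg, rng)
    if kind == "tumor":
        return init_tumor(cfg, rng)
    raise ValueError(f"unknown initializer kind: {kind!r}")


# ---------------------------------------------------------------------------
# metrics


def center_slice(grid: Grid, f: np.ndarray) -> np.ndarray:
    """Middle row of a cell field (mean of the two middle rows if ny even)."""
    ny = grid.ny
    if ny % 2:
        return f[:, ny // 2].copy()
    return 0.5 * (f[:, ny // 2 - 1] + f[:, ny // 2])


def metrics(state: PhaseState, ref_totals: np.ndarray) -> dict:
    """Summary metrics of a state: normalized cellular volume ν, normalized
    ECM volume μ, total tumor mass, and per-component domain maxima."""
    out: dict = {}
    totals = state.totals()
    for i, name in enumerate(state.names):
        out[f"total_{name}"] = float(totals[i])
        out[f"max_{name}"] = float(state.u[i].max())
    for alias, candidates in (("nu", ("cells", "live", "normal")),
                              ("mu", ("ecm",))):
        for cand in candidates:
            if cand in state.names:
                i = state.names.index(cand)
                if ref_totals[i] <= 0:
                    raise ZeroDivisionError(f"zero reference total for {cand}")
                out[alias] = float(totals[i] / ref_totals[i])
                break
    if "tumor" in state.names:
        out["tumor_mass"] = float(totals[state.names.index("tumor")])
    return out


# ---------------------------------------------------------------------------
# example registry


def _grid_for(L: float, h: float) -> Grid:
    n = int(round(L / h))
    return Grid(n, n, h)


def _example_1(name: str) -> ScenarioConfig:
    kin = Kinetics(b1_max=0.03, b2_max=3.0, u_ecm_opt=0.05)
    k = [0.0, 500.0, 300.0]
    ecm_damage = False
    if name == "1b":
        kin = replace(kin, b1_max=0.04)
    elif name == "1c":
        kin = replace(kin, b1_max=0.04)
        ecm_damage = True
    elif name == "1d":
        kin = replace(kin, b1_max=0.04, b2_max=4.0)
        ecm_damage = True
    mech = Mechanics.equal_drag(k, alpha_hat=1e6, u0_opt=0.25)
    return ScenarioConfig(
        name=name, grid=_grid_for(0.3, 0.01), names=("fluid", "cells", "ecm"),
        rate_law="regeneration", mech=mech, kin=kin,
        num=Numerics(dt=0.25, n_steps=21, beta=0.95),
        init={"kind": "regeneration", "wound_frac": 0.10, "ecm_damage": ecm_damage},
    )


def _example_2(name: str) -> ScenarioConfig:
    kin = Kinetics(b1_max=0.04, b3_max=2.0, d1_hat=0.01, d1_tilde=0.01, d2=0.5,
                   ell1=4e4, ell2=2e4, T1=2.0, T2=10.0, R1=0.25, R2=0.25,
                   u_ecm_opt=0.05)
    mech = Mechanics.equal_drag([0.0, 500.0, 600.0, 400.0], alpha_hat=0.8e6,
                                u0_opt=0.25)
    # delta = 2: with the fluid fraction near its 0.25 optimum, the
    # diffusivity exponent must exceed 1 for capillary-scale oxygen
    # heterogeneity (and hence a hypoxic response) to exist on this domain;
    # any delta > 0 is accepted in config
    chem = ChemicalParams(D_hat=173.0, delta=2.0, o_bar=30.0, o_cap=40.0)
    return ScenarioConfig(
        name=name, grid=_grid_for(0.3, 0.01),
        names=("fluid", "live", "dead", "ecm"), rate_law="oxygen_coupled",
        mech=mech, kin=kin,
        num=Numerics(dt=0.25, n_steps=51, beta=0.95),
        chem=chem,
        init={"kind": "regeneration", "wound_frac": 0.10, "fill_dead": True,
              "n_capillaries": 20, "hypoxic": name == "2h",
              "capillary_clear_radius": 8.0},
    )


def _example_3(name: str) -> ScenarioConfig:
    kin = Kinetics(b2_hat=0.9, d1_hat=0.06, d2_hat=0.06, b3_hat=50.0,
                   alpha=0.0, u_ecm_opt=0.05)
    k = [0.0, 1.0, 1.0, 25.0]
    init = {"kind": "tumor", "seed_size": 1}
    if name == "3a":
        kin = replace(kin, b3_hat=0.0)
    elif name == "3c":
        kin = replace(kin, alpha=1.0)
    elif name == "3c-nopassive":
        kin = replace(kin, alpha=50.0)
        k[3] = 0.0
    elif name == "3d":
        kin = replace(kin, b2_hat=1.2)
        init.update({"hetero": True, "zeta": 0.5, "noise_amp": 0.0012})
    mech = Mechanics.equal_drag(k, alpha_hat=1e6, u0_opt=0.25)
    return ScenarioConfig(
        name=name, grid=_grid_for(0.41, 0.01),
        names=("fluid", "normal", "tumor", "ecm"), rate_law="tumor",
        mech=mech, kin=kin,
        num=Numerics(dt=0.5, n_steps=500, beta=0.95),
        init=init,
    )


def _example_4() -> ScenarioConfig:
    # tumor sub-model used for calibration: only tumor kinetics active
    kin = Kinetics(b2_hat=0.9, d2_hat=0.0, d1_hat=0.0, b3_hat=0.0,
                   u_ecm_opt=0.05)
    mech = Mechanics.equal_drag([0.0, 1.0, 1.0, 25.0], alpha_hat=1e6, u0_opt=0.25)
    return ScenarioConfig(
        name="4", grid=_grid_for(0.41, 0.01),
        names=("fluid", "normal", "tumor", "ecm"), rate_law="tumor",
        mech=mech, kin=kin,
        num=Numerics(dt=0.25, n_steps=80, beta=0.90),
        init={"kind": "tumor", "seed_size": 1},
    )


_EXAMPLES = ("1a", "1b", "1c", "1d", "2", "2h",
             "3a", "3b", "3c", "3c-nopassive", "3d", "4")


def list_examples() -> tuple[str, ...]:
    return _EXAMPLES


def example_config(name: str) -> ScenarioConfig:
    """A fresh configuration for one of the named in-package examples."""
    if name in ("1a", "1b", "1c", "1d"):
        return _example_1(name)
    if name in ("2", "2h"):
        return _example_2(name)
    if name in ("3a", "3b", "3c", "3c-nopassive", "3d"):
        return _example_3(name)
    if name == "4":
        return _example_4()
    raise KeyError(f"unknown example {name!r}; available: {', '.join(_EXAMPLES)}")
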