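"""Parameter blocks: mechanical, kinetic, chemical and numerical.

Units follow the tissue-mechanics convention used throughout the package:
lengths in mm, time in days, stresses via strain-stress coefficients k_i in
kg·mm²/day², drag coefficients in kg/day, oxygen partial pressure in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

FieldOrScalar = Union[float, np.ndarray]


def positive_part(x):
    """The (·)+ operator: max(·, 0), with one-sided derivative 0 at the kink."""
    return np.maximum(x, 0.0)


@dataclass
class Mechanics:
    """Excess-pressure stress and drag parameters.

    ``k`` holds one strain-stress coefficient per component (the fluid entry
    is ignored and treated as 0: the fluid carries no excess pressure).
    ``drag`` is the symmetric matrix of pairwise friction coefficients
    α̂_ij > 0; its diagonal is unused.  ``u0_opt`` is the optimal
    interstitial-fluid fraction, a scalar or a cell field.
    """

    k: np.ndarray
    drag: np.ndarray
    u0_opt: FieldOrScalar = 0.25

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.drag = np.asarray(self.drag, dtype=float)
        if np.any(self.k < 0):
            raise ValueError("strain-stress coefficients k_i must be >= 0")
        n = len(self.k)
        if self.drag.shape != (n, n):
            raise ValueError(f"drag matrix must be {(n, n)}, got {self.drag.shape}")
        off = self.drag[~np.eye(n, dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("drag coefficients must be strictly positive")
        if np.any(np.asarray(self.u0_opt) <= 0) or np.any(np.asarray(self.u0_opt) >= 1):
            raise ValueError("u0_opt must lie strictly inside (0, 1)")

    @classmethod
    def equal_drag(cls, k: Sequence[float], alpha_hat: float,
                   u0_opt: FieldOrScalar = 0.25) -> "Mechanics":
        n = len(k)
        drag = np.full((n, n), float(alpha_hat))
        np.fill_diagonal(drag, 0.0)
        return cls(np.asarray(k, dtype=float), drag, u0_opt)


@dataclass
class Kinetics:
    """Growth/decay coefficients for the scenario rate laws (day^-1 unless
    noted).  Only the fields a given rate law reads need to be set.

    Regeneration laws: ``b1_max`` (cell growth trigger scale), ``b2_max``
    (ECM secretion scale), ``u_ecm_opt``.

    Oxygen-coupled laws additionally: ``b3_max`` (ECM), ``d1_hat``/``d1_tilde``
    (fluid-starvation / hypoxic death of live cells), ``d2`` (dead-cell
    disintegration), thresholds ``T1 < T2`` (mmHg) and steepnesses
    ``R1``, ``R2`` of the tanh response curves, consumption rates
    ``ell1``/``ell2``.

    Tumor laws: ``d1_hat`` (normal-cell starvation death), ``b2_hat``/
    ``d2_hat`` (tumor proliferation/decay), ``b3_hat`` (ECM remodeling),
    ``alpha`` (active-response inflation of the ECM target), ``u_ecm_opt``.
    """

    b1_max: float = 0.0
    b2_max: float = 0.0
    b3_max: float = 0.0
    b2_hat: float = 0.0
    d2_hat: float = 0.0
    b3_hat: float = 0.0
    d1_hat: float = 0.0
    d1_tilde: float = 0.0
    d2: float = 0.0
    ell1: float = 0.0
    ell2: float = 0.0
    T1: float = 2.0
    T2: float = 10.0
    R1: float = 0.25
    R2: float = 0.25
    alpha: float = 0.0
    u_ecm_opt: FieldOrScalar = 0.05

    def __post_init__(self) -> None:
        for name in ("b1_max", "b2_max", "b3_max", "b2_hat", "d2_hat", "b3_hat",
                     "d1_hat", "d1_tilde", "d2", "ell1", "ell2", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"kinetic coefficient {name} must be >= 0")
        if not self.T1 < self.T2:
            raise ValueError("hypoxic thresholds must satisfy T1 < T2")


@dataclass
class ChemicalParams:
    """Steady-state chemical (oxygen) transport parameters.

    ``D_hat`` (mm²/day) scales the fluid-dependent diffusivity
    ``D = D_hat · u0^delta``; ``o_bar`` is the domain-boundary Dirichlet
    value and ``o_cap`` the capillary value(s), both in mmHg.
    ``capillaries`` is an (m, 2) integer array of interior cell indices.
    """

    D_hat: float = 173.0
    delta: float = 0.5
    o_bar: float = 30.0
    o_cap: FieldOrScalar = 40.0
    capillaries: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    decay: float = 0.0  # natural decay rate λ (day^-1)

    def __post_init__(self) -> None:
        if self.D_hat <= 0:
            raise ValueError("diffusion scale D_hat must be positive")
        if self.delta <= 0:
            raise ValueError("diffusivity exponent delta must be positive")
        if self.o_bar < 0 or np.any(np.asarray(self.o_cap) < 0):
            raise ValueError("boundary and capillary values must be >= 0")
        self.capillaries = np.asarray(self.capillaries, dtype=int).reshape(-1, 2)

    def capillary_values(self, rng: Optional[np.random.Generator] = None,
                         jitter: float = 0.0) -> np.ndarray:
        """Prescribed value per capillary; optionally randomized per source."""
        vals = np.broadcast_to(np.asarray(self.o_cap, dtype=float),
                               (len(self.capillaries),)).copy()
        if jitter > 0.0:
            if rng is None:
                raise ValueError("randomized capillary values need an rng")
            vals += rng.uniform(-jitter, jitter, size=len(vals))
        return vals


@dataclass
class Numerics:
    """Time-stepping and solver controls.

    ``beta`` caps the total non-fluid fraction after each corrector step so
    that at least ``1 - beta`` of every cell remains interstitial fluid.
    ``rhs_sign=+1`` uses the momentum-balance right-hand side
    ``u_i∇Σu_jΨ_j − ∇(u_iΨ_i)``; ``-1`` flips it (sensitivity runs only).
    ``drag_divide`` selects the drag interpretation in the stability bound.
    """

    dt: float = 0.25
    n_steps: int = 100
    beta: float = 0.95
    newton_tol: float = 1e-9
    newton_max_iter: int = 50
    seed: int = 0
    snapshot_every: int = 0  # 0 = only first/last
    chem_every_stage: bool = True
    rhs_sign: int = 1
    drag_divide: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        if self.rhs_sign not in (1, -1):
            raise ValueError("rhs_sign must be +1 or -1")
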