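"""Mixture state: volume fractions per component plus solved chemical fields.

Component 0 is always the interstitial fluid; by convention the
extracellular matrix, when present, is the last component.  The no-voids
condition Σ_i u_i = 1 is maintained by computing the fluid fraction by
closure rather than integrating its own balance equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid

__all__ = ["PhaseState"]


@dataclass
class PhaseState:
    grid: Grid
    names: tuple[str, ...]
    u: np.ndarray  # (ncomp, nx, ny), u[0] is interstitial fluid
    chem: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (len(self.names),) + self.grid.shape:
            raise ValueError(
                f"u has shape {self.u.shape}, expected "
                f"{(len(self.names),) + self.grid.shape}"
            )
        if self.names[0] != "fluid":
            raise ValueError("component 0 must be the interstitial fluid")

    @classmethod
    def uniform(cls, grid: Grid, names: tuple[str, ...], fractions) -> "PhaseState":
        fractions = np.asarray(fractions, dtype=float)
        if len(fractions) != len(names):
            raise ValueError("one fraction per component required")
        u = np.broadcast_to(fractions[:, None, None], (len(names),) + grid.shape).copy()
        return cls(grid, names, u)

    @property
    def ncomp(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def close_fluid(self) -> None:
        """Enforce the no-voids condition by solving for the fluid fraction."""
        self.u[0] = 1.0 - self.u[1:].sum(axis=0)

    def totals(self) -> np.ndarray:
        """Domain total of each component's volume fraction (grid-cell sum)."""
        return self.u.sum(axis=(1, 2))

    def copy(self) -> "PhaseState":
        return PhaseState(self.grid, self.names, self.u.copy(),
                          {k: v.copy() for k, v in self.chem.items()})

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.u < -atol) or np.any(self.u > 1 + atol):
            raise ValueError("volume fractions outside [0, 1]")
        if not np.allclose(self.u.sum(axis=0), 1.0, atol=atol):
            raise ValueError("no-voids condition violated: volume fractions do not sum to 1")
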