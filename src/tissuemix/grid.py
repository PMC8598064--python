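"""Rectangular staggered grid and discrete differential operators.

Scalars (volume fractions, chemical fields, rates) live at cell centers;
advective fluxes and gradients live at faces (half-index locations between
adjacent cells, plus the boundary faces of the domain).

Conventions
-----------
* Cells are indexed ``(i, j)`` with ``i`` along x and ``j`` along y,
  0-based, lower-left origin.  Cell ``(i, j)`` is centered at
  ``((i + 1/2) h, (j + 1/2) h)``.
* A cell field is an ``(nx, ny)`` array.
* x-faces form an ``(nx+1, ny)`` array: face ``(i, j)`` sits between cells
  ``(i-1, j)`` and ``(i, j)``; ``i = 0`` and ``i = nx`` are boundary faces.
  y-faces are ``(nx, ny+1)`` analogously.
* The divergence is the conservative finite-volume form, so the discrete
  divergence theorem holds to round-off and the composition
  ``divergence(gradient(f))`` is the standard 5-point Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Grid",
    "FaceField",
    "gradient_faces",
    "divergence_cells",
    "face_average",
    "faces_to_cells",
    "grad_norm_sq",
]


@dataclass(frozen=True)
class Grid:
    """Cell-centered rectangular mesh with spacing ``h`` (mm)."""

    nx: int
    ny: int
    h: float

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError(f"grid must be at least 3x3, got {self.nx}x{self.ny}")
        if self.h <= 0:
            raise ValueError(f"grid spacing must be positive, got h={self.h}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def extent(self) -> tuple[float, float]:
        """Domain side lengths (Lx, Ly) in mm."""
        return (self.nx * self.h, self.ny * self.h)

    @property
    def xc(self) -> np.ndarray:
        """x coordinates of cell centers, shape (nx,)."""
        return (np.arange(self.nx) + 0.5) * self.h

    @property
    def yc(self) -> np.ndarray:
        """y coordinates of cell centers, shape (ny,)."""
        return (np.arange(self.ny) + 0.5) * self.h

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-center coordinates, each shaped (nx, ny)."""
        return np.meshgrid(self.xc, self.yc, indexing="ij")

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)

    def check_cell(self, f: np.ndarray, what: str = "cell field") -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if f.shape != self.shape:
            raise ValueError(f"{what} has shape {f.shape}, expected {self.shape}")
        return f


@dataclass
class FaceField:
    """A staggered vector field: one scalar per x-face and per y-face."""

    x: np.ndarray  # (nx+1, ny)
    y: np.ndarray  # (nx, ny+1)

    @classmethod
    def zeros(cls, grid: Grid) -> "FaceField":
        return cls(np.zeros((grid.nx + 1, grid.ny)), np.zeros((grid.nx, grid.ny + 1)))

    def check(self, grid: Grid, what: str = "face field") -> "FaceField":
        if self.x.shape != (grid.nx + 1, grid.ny) or self.y.shape != (grid.nx, grid.ny + 1):
            raise ValueError(
                f"{what} has shapes {self.x.shape}/{self.y.shape}, expected "
                f"{(grid.nx + 1, grid.ny)}/{(grid.nx, grid.ny + 1)}"
            )
        return self

    def copy(self) -> "FaceField":
        return FaceField(self.x.copy(), self.y.copy())

    def __add__(self, other: "FaceField") -> "FaceField":
        return FaceField(self.x + other.x, self.y + other.y)

    def __mul__(self, a: float) -> "FaceField":
        return FaceField(self.x * a, self.y * a)

    __rmul__ = __mul__

    def __neg__(self) -> "FaceField":
        return FaceField(-self.x, -self.y)


def gradient_faces(grid: Grid, f: np.ndarray, boundary: float = 0.0) -> FaceField:
    """Centered difference of a cell field across each interior face.

    Interior x-face value is ``(f[i, j] - f[i-1, j]) / h``; boundary faces
    carry ``boundary`` (default 0, a homogeneous Neumann-like closure for a
    sealed tissue sample).
    """
    f = grid.check_cell(f)
    g = FaceField.zeros(grid)
    g.x[1:-1, :] = (f[1:, :] - f[:-1, :]) / grid.h
    g.y[:, 1:-1] = (f[:, 1:] - f[:, :-1]) / grid.h
    if boundary != 0.0:
        g.x[0, :] = g.x[-1, :] = boundary
        g.y[:, 0] = g.y[:, -1] = boundary
    return g


def divergence_cells(grid: Grid, q: FaceField) -> np.ndarray:
    """Conservative finite-volume divergence of a face flux back to cells."""
    q.check(grid)
    return (q.x[1:, :] - q.x[:-1, :]) / grid.h + (q.y[:, 1:] - q.y[:, :-1]) / grid.h


def face_average(grid: Grid, f: np.ndarray) -> FaceField:
    """Arithmetic mean of the two adjacent cells at each interior face;
    boundary faces take the adjacent cell value."""
    f = grid.check_cell(f)
    a = FaceField.zeros(grid)
    a.x[1:-1, :] = 0.5 * (f[1:, :] + f[:-1, :])
    a.x[0, :] = f[0, :]
    a.x[-1, :] = f[-1, :]
    a.y[:, 1:-1] = 0.5 * (f[:, 1:] + f[:, :-1])
    a.y[:, 0] = f[:, 0]
    a.y[:, -1] = f[:, -1]
    return a


def faces_to_cells(grid: Grid, q: FaceField) -> tuple[np.ndarray, np.ndarray]:
    """Average the two x-faces (resp. y-faces) of each cell back to its center.

    Returns the (x, y) components of the collocated vector field.
    """
    q.check(grid)
    cx = 0.5 * (q.x[1:, :] + q.x[:-1, :])
    cy = 0.5 * (q.y[:, 1:] + q.y[:, :-1])
    return cx, cy


def grad_norm_sq(grid: Grid, f: np.ndarray) -> np.ndarray:
    """Cell-centered squared gradient magnitude ``‖∇f‖²``.

    Computed as the average of the squared x-face differences over a cell's
    two x-faces plus the same for y, which keeps the quantity symmetric
    under the grid's dihedral symmetries.
    """
    g = gradient_faces(grid, f)
    sx = 0.5 * (g.x[1:, :] ** 2 + g.x[:-1, :] ** 2)
    sy = 0.5 * (g.y[:, 1:] ** 2 + g.y[:, :-1] ** 2)
    return sx + sy
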