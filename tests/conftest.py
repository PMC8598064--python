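import warnings

import numpy as np
import pytest

from tissuemix.grid import Grid
from tissuemix.params import Mechanics
from tissuemix.state import PhaseState

# the worst-case time-step bound is intentionally violated by the
# paper-scale configurations; the runner warns, tests need not care
warnings.filterwarnings("ignore", message="time step dt=.*stability")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    return Grid(6, 5, 0.1)


def random_state(grid: Grid, rng, ncomp: int = 3,
                 names: tuple[str, ...] | None = None) -> PhaseState:
    """A valid random mixture state: positive fractions summing to one,
    with a healthy share of interstitial fluid."""
    if names is None:
        names = ("fluid",) + tuple(f"c{i}" for i in range(1, ncomp))
    raw = rng.uniform(0.05, 1.0, size=(ncomp,) + grid.shape)
    u = raw / raw.sum(axis=0) * 0.8
    u[0] = 1.0 - u[1:].sum(axis=0)
    return PhaseState(grid, names, u)


def random_mechanics(rng, ncomp: int, equal_drag: bool = False) -> Mechanics:
    k = np.concatenate([[0.0], rng.uniform(1.0, 500.0, ncomp - 1)])
    if equal_drag:
        return Mechanics.equal_drag(k, alpha_hat=rng.uniform(1e5, 1e6))
    drag = rng.uniform(1e5, 1e6, size=(ncomp, ncomp))
    drag = 0.5 * (drag + drag.T)
    np.fill_diagonal(drag, 0.0)
    return Mechanics(k, drag, u0_opt=0.25)
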