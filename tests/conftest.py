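import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from qmethod.grid import GridSpec
from qmethod.panel import QSortPanel
from qmethod.study import load_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fx():
    """The packaged study fixture (statements, grid, arrays, demographics)."""
    return load_fixture()


@pytest.fixture(scope="session")
def study_grid(fx):
    return fx.grid


@pytest.fixture
def tiny_grid():
    """Minimal symmetric grid: one statement at each of -1, 0, +1."""
    return GridSpec({-1: 1, 0: 1, 1: 1})


@pytest.fixture
def small_grid():
    """Nine statements on -2..+2 with capacities 1,2,3,2,1."""
    return GridSpec({-2: 1, -1: 2, 0: 3, 1: 2, 2: 1})


def panel_from_columns(columns: dict, grid) -> QSortPanel:
    n = len(next(iter(columns.values())))
    sorts = pd.DataFrame(columns, index=pd.Index(range(1, n + 1), name="statement_id"))
    return QSortPanel(sorts, grid)


@pytest.fixture
def arrays_panel(fx):
    """The five published factor arrays treated as a 5-sort panel."""
    sorts = fx.factor_arrays.copy()
    sorts.columns = [f"exemplar_{i + 1}" for i in range(sorts.shape[1])]
    return QSortPanel(sorts, fx.grid, fx.statements)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
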