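import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from gbspheroid.lattice import CellGrid, Phenotype
from gbspheroid.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small, fast simulation: 1.5 mm domain (~83x83 sites), 4 days."""
    return SimulationConfig(
        L_mm=1.5,
        cell_size_um=18.0,
        duration_days=4.0,
        initial_cells=100,
        phenotypes=(Phenotype(0, 24.0, 2),),
        seed=7,
    )


def make_grid(n=7, dt=24.0, r=2, cell_size=18.0):
    return CellGrid(n, cell_size, [Phenotype(0, dt, r)])


def fill_sites(grid, sites, age=0.0, pid=0):
    for s in sites:
        grid.add_cell(s, pid, age)
    return grid
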