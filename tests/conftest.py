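import numpy as np
import pytest

from cobenefits import ahmedabad
from cobenefits.grids import (
    AgeStructure,
    AnnualSurface,
    ConcentrationField,
    GridSpec,
    PopulationSurface,
    default_calendar,
)


@pytest.fixture
def grid5():
    return GridSpec(5, 5)


@pytest.fixture
def grid8():
    return GridSpec(8, 8)


@pytest.fixture
def calendar():
    return default_calendar()


@pytest.fixture
def pop_2018():
    return ahmedabad.POPULATION["2018"]


@pytest.fixture
def pop_2030():
    return ahmedabad.POPULATION["2030"]


def uniform_fields(grid, means):
    """One constant field per representative month."""
    return {
        m: ConcentrationField(grid, m, np.full(grid.shape, v))
        for m, v in means.items()
    }


def uniform_surface(grid, value, scenario=""):
    return AnnualSurface(grid, np.full(grid.shape, float(value)), scenario=scenario)


def uniform_population(grid, age_structure):
    per_cell = age_structure.total_0_99 / grid.n_cells
    return PopulationSurface(grid, np.full(grid.shape, per_cell), age_structure)


@pytest.fixture
def random_surface_pair(grid8):
    rng = np.random.default_rng(7)
    ref = AnnualSurface(grid8, rng.uniform(40, 90, grid8.shape))
    scen = AnnualSurface(grid8, rng.uniform(40, 90, grid8.shape))
    return ref, scen


@pytest.fixture
def random_population(grid8, pop_2030):
    rng = np.random.default_rng(11)
    persons = rng.uniform(1e3, 1e5, grid8.shape)
    persons *= pop_2030.total_0_99 / persons.sum()
    return PopulationSurface(grid8, persons, pop_2030)
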