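import numpy as np
import pytest

from irmap import (
    LifeHistoryParameters,
    ModelParameters,
    RasterGrid,
    load_presets,
)


@pytest.fixture(scope="session")
def table1_params() -> ModelParameters:
    """Calibrated baseline: r = gamma = 0.75, beta = 1, N = 50."""
    return ModelParameters(**load_presets()["model"]["table1"])


@pytest.fixture(scope="session")
def parham_lh() -> LifeHistoryParameters:
    """Working life-history preset (a = -0.03)."""
    return LifeHistoryParameters(**load_presets()["life_history"]["parham2010"])


@pytest.fixture(scope="session")
def printed_lh() -> LifeHistoryParameters:
    """Life-history constants with the printed a = -0.3."""
    return LifeHistoryParameters(
        **load_presets()["life_history"]["table1_as_printed"]
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240429)


def grid_of(values, origin=(0.0, 0.0), cellsize=1.0) -> RasterGrid:
    return RasterGrid(values=np.asarray(values, dtype=float), origin=origin, cellsize=cellsize)


@pytest.fixture()
def make_grid():
    return grid_of
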