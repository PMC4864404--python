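import numpy as np
import pytest
from hypothesis import settings

from geopoverty.grids import GridLayer, LayerStack
from geopoverty.synthetic import LandscapeConfig, PanelConfig, generate_landscape, generate_panel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def _layer(values, kind, nodata=-9999.0):
    return GridLayer(np.asarray(values, dtype=float), kind=kind, nodata=nodata)


@pytest.fixture
def toy_stack():
    """4x4 single-country stack: 8 agricultural cells, 3 degrading (2 remote).

    Expected labels: DAL_REM at (0,0),(0,1); DAL_ACC at (0,2); the five
    remaining agricultural cells are IAL (all accessible). Population is
    10 persons/cell everywhere and there is no urban land.
    """
    npp = np.ones((4, 4))
    npp[0, 0] = npp[0, 1] = npp[0, 2] = -5.0
    agri = np.zeros((4, 4))
    agri[0, :] = 1.0
    agri[1, :] = 1.0
    travel = np.ones((4, 4))
    travel[0, 0] = travel[0, 1] = 6.0
    return LayerStack(
        npp_trend=_layer(npp, "npp_trend"),
        agri_mask=_layer(agri, "mask"),
        urban_mask=_layer(np.zeros((4, 4)), "mask"),
        travel_time=_layer(travel, "travel_time"),
        population_2000=_layer(np.full((4, 4), 10.0), "population"),
        population_2010=_layer(np.full((4, 4), 11.3), "population"),
        country_zone=_layer(np.ones((4, 4)), "zone"),
        region_map={1: "SSA"},
        country_names={1: "Toyland"},
    )


@pytest.fixture(scope="session")
def default_landscape():
    return generate_landscape(LandscapeConfig(seed=42))


@pytest.fixture(scope="session")
def default_panel():
    return generate_panel(PanelConfig(seed=42))
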