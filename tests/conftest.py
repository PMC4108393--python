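import numpy as np
import pytest

import wolftracks as wt
from wolftracks.scenarios import (
    ScenarioConfig,
    _survey_density,
    build_library,
    scenario_landscape,
)

EXTENT = (120_000.0, 120_000.0)


@pytest.fixture(scope="session")
def extent():
    return EXTENT


@pytest.fixture(scope="session")
def grids_all(extent):
    return [wt.build_grid(extent, a) for a in wt.GRID_AREAS_KM2]


@pytest.fixture(scope="session")
def flat_raster(extent):
    """Spatially near-uniform habitat surface (degenerate smoothing)."""
    return wt.generate_rsf_surface(extent, 2000.0, extent[0], seed=1, pad=60_000.0)


@pytest.fixture(scope="session")
def density1_occupancies():
    """Mean occupancy at 1 pack/1,000 km2, December movements, for the
    cohesive (1 hunting unit) and split (4 hunting units) scenarios on the
    36 and 576 km2 grids; 10 replicate surveys each drawing from the full
    1,000-path-per-territory library of the survey protocol."""
    cfg = ScenarioConfig(
        month="December",
        densities=(1.0,),
        grid_areas=(36.0, 576.0),
        seed=0,
    )
    land = scenario_landscape(cfg)
    _, lib = build_library(cfg, 1.0, land)
    occ = {}
    for hu in (1, 4):
        rows = _survey_density(cfg.with_(hunting_units=hu), 1.0, lib, land)
        for r in rows:
            occ[(r["grid_km2"], hu)] = r["mean_occupancy"]
    return occ


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
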