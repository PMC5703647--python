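import numpy as np
import pytest

from epivertex.dynamics import (
    ModelParams,
    init_tension_state,
    run_simulation,
)
from epivertex.tissue import Box, build_honeycomb, build_voronoi


@pytest.fixture()
def honeycomb44():
    return build_honeycomb(4, 4, 1.0)


@pytest.fixture()
def voronoi_small():
    return build_voronoi(12, seed=5, box=Box(3.5, 3.5))


@pytest.fixture()
def wt_params():
    return ModelParams(seed=0)


@pytest.fixture()
def random_tissue_state():
    """Small random tissue with heterogeneous tensions and areas."""
    tissue = build_voronoi(12, seed=5, box=Box(3.5, 3.5))
    rng = np.random.default_rng(0)
    tissue.preferred_areas = rng.normal(1.0, 0.19, tissue.n_cells)
    params = ModelParams(seed=1)
    tension = init_tension_state(tissue, params, rng)
    tension.gamma = tension.gamma0 * rng.uniform(0.5, 1.5, tissue.n_edges)
    return tissue, tension, params


@pytest.fixture(scope="session")
def short_wt_run():
    """One short wild-type run shared across tests (12 min + 3 burn-in)."""
    return run_simulation(
        ModelParams(seed=11), n_cells=64, duration=12.0, burn_in=3.0,
        keep_tissues=True,
    )


@pytest.fixture(scope="session")
def raster_movie(short_wt_run):
    from epivertex.fixtures import RasterConfig, rasterize_movie

    return rasterize_movie(short_wt_run, RasterConfig(px_per_l=25, seed=3))
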