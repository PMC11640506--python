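import warnings

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("repro", derandomize=True, database=None)
hypothesis_settings.load_profile("repro")

from seastock import SimConfig, simulate_fishery
from seastock.seasonal import (
    ModelData,
    SeasonalModelConfig,
    fit_seasonal_model,
)
from seastock.spatial import build_knot_mesh, make_grid


def small_sim(**overrides):
    """A small, fast simulation frame shared by several test modules."""
    base = dict(
        n_years=3,
        lon_min=147.0,
        lon_max=151.0,
        lat_min=37.0,
        lat_max=41.0,
        cell_deg=0.5,
        records_per_cell_month=0.3,
        n_vessels=6,
        seed=11,
    )
    base.update(overrides)
    return SimConfig.desk(**base)


def fit_on(cfg, n_knots=8, model_config=None, mesh_seed=0):
    records, truth = simulate_fishery(cfg)
    extrap = make_grid(cfg.lon_min, cfg.lon_max, cfg.lat_min, cfg.lat_max, cfg.cell_deg)
    mesh = build_knot_mesh(
        records["lon"].to_numpy(), records["lat"].to_numpy(), extrap, n_knots,
        seed=mesh_seed,
    )
    data = ModelData.from_records(records, mesh)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_seasonal_model(data, mesh, model_config or SeasonalModelConfig())
    return fit, records, truth


@pytest.fixture(scope="session")
def tiny_fit():
    """One small seasonal fit reused across unit tests (3 years, 8 knots)."""
    cfg = small_sim()
    fit, records, truth = fit_on(cfg, n_knots=8, mesh_seed=1)
    return {"fit": fit, "records": records, "truth": truth, "config": cfg}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
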