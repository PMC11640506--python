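"""Fitting behaviour of the seasonal model on small synthetic frames."""

import dataclasses
import warnings

import numpy as np
import pytest

from seastock.seasonal import (
    ModelData,
    SeasonalModelConfig,
    cog_from_fields,
    compute_cog,
    compute_index,
    fit_seasonal_model,
    index_from_fields,
)
from seastock.simulate import simulate_fishery
from seastock.spatial import build_knot_mesh, make_grid

from conftest import fit_on, small_sim


def test_tiny_fit_meets_convergence_contract(tiny_fit):
    diag = tiny_fit["fit"].diagnostics
    assert diag.max_gradient <= 1e-4
    assert diag.hessian_pd
    assert diag.converged
    assert diag.n_random > diag.n_fixed


def test_index_has_one_positive_entry_per_step(tiny_fit):
    fit = tiny_fit["fit"]
    idx = compute_index(fit, n_draws=40, seed=0)
    assert len(idx) == fit.data.n_steps
    assert (idx["index"] > 0).all()
    assert (idx["se"] > 0).all()
    assert np.allclose(idx["cv"], idx["se"] / idx["index"])


def test_index_tracks_latent_truth(tiny_fit):
    idx = compute_index(tiny_fit["fit"], n_draws=20, seed=1)
    corr = np.corrcoef(
        np.log(idx["index"].to_numpy()), np.log(tiny_fit["truth"].true_index)
    )[0, 1]
    assert corr > 0.8


def test_cog_stays_inside_region(tiny_fit):
    fit = tiny_fit["fit"]
    cog = compute_cog(fit)
    x, y = fit.mesh.knots_km[:, 0], fit.mesh.knots_km[:, 1]
    pad = 30.0
    assert cog["easting_km"].between(x.min() - pad, x.max() + pad).all()
    assert cog["northing_km"].between(y.min() - pad, y.max() + pad).all()


def test_index_from_fields_forced_examples():
    # single knot: D_t = a * n * w
    d = index_from_fields(np.array([2.0]), np.array([[3.0]]), np.array([[5.0]]))
    assert d[0] == 30.0
    # uniform fields: D_t = n * w * sum(a_s)
    area = np.array([1.0, 2.0, 3.0])
    n = np.full((3, 2), 4.0)
    w = np.full((3, 2), 0.5)
    np.testing.assert_allclose(index_from_fields(area, n, w), [12.0, 12.0])
    with pytest.raises(ValueError):
        index_from_fields(np.zeros(2), n[:2], w[:2])


def test_cog_from_fields_symmetry_and_point_mass():
    coords = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]])
    area = np.ones(3)
    sym = np.array([[1.0], [5.0], [1.0]])
    cog = cog_from_fields(area, coords, sym, np.ones_like(sym))
    assert cog[0, 0] == pytest.approx(100.0)
    point = np.array([[0.0], [0.0], [7.0]])
    cog2 = cog_from_fields(area, coords, point + 1e-300, np.ones_like(point))
    assert cog2[0, 0] == pytest.approx(200.0)


def test_offset_rescaling_only_shifts_index_scale():
    """Multiplying all offsets by k rescales the density field by 1/k and
    leaves the index trend (log-differences) unchanged."""
    cfg = small_sim(n_years=2, seed=19, records_per_cell_month=0.35)
    records, _ = simulate_fishery(cfg)
    extrap = make_grid(cfg.lon_min, cfg.lon_max, cfg.lat_min, cfg.lat_max, cfg.cell_deg)
    mesh = build_knot_mesh(
        records["lon"].to_numpy(), records["lat"].to_numpy(), extrap, 6, seed=0
    )
    data = ModelData.from_records(records, mesh)
    model_cfg = SeasonalModelConfig(check_hessian=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit1 = fit_seasonal_model(data, mesh, model_cfg)
        fit2 = fit_seasonal_model(
            dataclasses.replace(data, a=2.0 * data.a), mesh, model_cfg
        )
    d1 = compute_index(fit1, n_draws=5, seed=0)["index"].to_numpy()
    d2 = compute_index(fit2, n_draws=5, seed=0)["index"].to_numpy()
    ratio = d2 / d1
    np.testing.assert_allclose(ratio, 0.5, rtol=0.05)
    np.testing.assert_allclose(np.diff(np.log(d2)), np.diff(np.log(d1)), atol=0.03)


def test_spatial_sds_shrink_when_truth_has_none():
    """Data generated with zero spatial field SDs drive the estimated
    spatial SDs toward zero (well below the observation noise)."""
    # dense sampling: with few records per knot-step the profile likelihood
    # in a field SD is nearly flat near zero and its MLE is noisy
    cfg = small_sim(
        seed=23,
        sigma_omega=0.0, sigma_xi_season=0.0, sigma_xi_year=0.0,
        sigma_epsilon=0.0, hotspot_amplitude=0.0,
        cog_drift_km_per_year=0.0, trend_log_per_year=0.0,
        records_per_cell_month=2.0,
    )
    fit, _, _ = fit_on(
        cfg, n_knots=8, model_config=SeasonalModelConfig(check_hessian=False),
        mesh_seed=2,
    )
    p = fit.params
    for sd in (p.sigma_omega_n, p.sigma_omega_w, p.sigma_season_n,
               p.sigma_season_w, p.sigma_year_n, p.sigma_year_w,
               p.sigma_eps_n, p.sigma_eps_w):
        assert sd <= 0.1 * p.sigma_obs


def test_degenerate_data_rejected(tiny_fit):
    records = tiny_fit["records"]
    mesh = tiny_fit["fit"].mesh
    all_zero = records.copy()
    all_zero["catch_kg"] = 0.0
    with pytest.raises(ValueError, match="all-zero or all-positive"):
        ModelData.from_records(all_zero, mesh)
    all_pos = records.copy()
    all_pos["catch_kg"] = 1.0
    with pytest.raises(ValueError, match="all-zero or all-positive"):
        ModelData.from_records(all_pos, mesh)


def test_step_without_positives_rejected(tiny_fit):
    records = tiny_fit["records"].copy()
    mesh = tiny_fit["fit"].mesh
    first_spring = (records["year"] == records["year"].min()) & (
        records["month"] <= 5
    )
    records.loc[first_spring, "catch_kg"] = 0.0
    with pytest.raises(ValueError, match="spring"):
        ModelData.from_records(records, mesh)
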