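"""Poisson-link primitives and the joint likelihood, against closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seastock.seasonal import (
    ModelData,
    SeasonalModelParams,
    assemble_linear_predictors,
    data_negative_log_likelihood,
    encounter_prob,
    negative_log_likelihood,
    positive_rate,
)
from seastock.spatial import KnotMesh

LOG_2PI = np.log(2 * np.pi)


def test_encounter_prob_closed_forms():
    assert encounter_prob(0.0, 5.0) == 0.0
    assert encounter_prob(1.0, np.log(2)) == pytest.approx(0.5, abs=1e-15)
    assert encounter_prob(10.0, 5.0) == pytest.approx(1.0, abs=1e-15)
    with pytest.raises(ValueError):
        encounter_prob(-1.0, 1.0)


def test_positive_rate_closed_form_and_limit():
    assert positive_rate(1.0, np.log(2), 3.0) == pytest.approx(6 * np.log(2))
    # c -> w as a*n -> 0+ (series limit of a*n / (1 - exp(-a*n)))
    assert positive_rate(1e-10, 1.0, 7.0) == pytest.approx(7.0, rel=1e-6)
    with pytest.raises(ValueError):
        positive_rate(0.0, 1.0, 2.0)


@settings(max_examples=200, deadline=None)
@given(
    a=st.floats(min_value=1e-6, max_value=50.0),
    n=st.floats(min_value=1e-6, max_value=50.0),
    w=st.floats(min_value=1e-3, max_value=1e4),
)
def test_poisson_link_identity_exact(a, n, w):
    """c * p = a * n * w holds to machine precision for any valid input."""
    p = encounter_prob(a, n)
    c = positive_rate(a, n, w)
    assert c * p == pytest.approx(a * n * w, rel=1e-12)


# --- tiny hand-built model -------------------------------------------------

def _toy_mesh(n_knots=2):
    coords = np.column_stack([np.linspace(0, 100, n_knots), np.zeros(n_knots)])
    return KnotMesh(
        knots_lonlat=coords / 111.32,
        knots_km=coords,
        area_km2=np.full(n_knots, 50.0),
        origin=(0.0, 0.0),
        ref_lat=0.0,
    )


def _toy_data(b, a, knot, season, year, vessel, n_seasons=2, n_years=1):
    b = np.asarray(b, dtype=float)
    season = np.asarray(season)
    year = np.asarray(year)
    rows = []
    for iy in range(n_years):
        for iu in range(n_seasons):
            rows.append({"t": iy * n_seasons + iu, "year": 2014 + iy,
                         "year_idx": iy, "season": f"s{iu}", "season_idx": iu})
    return ModelData(
        b=b, a=np.asarray(a, dtype=float), knot=np.asarray(knot),
        season_idx=season, year_idx=year,
        time_idx=year * n_seasons + season,
        vessel_idx=np.asarray(vessel),
        times=pd.DataFrame(rows),
        seasons=tuple(f"s{i}" for i in range(n_seasons)),
        years=np.arange(2014, 2014 + n_years),
        vessels=np.array(["V1", "V2"]),
        n_knots=2,
    )


def _toy_params(**kw):
    return SeasonalModelParams.zeros(
        n_knots=2, n_seasons=2, n_years=1, n_vessels=2,
        sigma_obs=kw.pop("sigma_obs", 0.5), range_km=50.0, **kw,
    )


def test_assemble_matches_per_term_oracle():
    rng = np.random.default_rng(0)
    params = _toy_params()
    for name in ("beta_n", "beta_w", "omega_n", "omega_w", "xi_season_n",
                 "xi_season_w", "xi_year_n", "xi_year_w", "eps_n", "eps_w",
                 "vessel_n", "vessel_w"):
        arr = getattr(params, name)
        setattr(params, name, rng.standard_normal(arr.shape))
    data = _toy_data(
        b=[0, 5.0, 3.0, 0], a=[1, 2, 1, 3], knot=[0, 1, 0, 1],
        season=[0, 0, 1, 1], year=[0, 0, 0, 0], vessel=[0, 1, 1, 0],
    )
    log_n, log_w = assemble_linear_predictors(params, data)
    for i in range(data.n_obs):
        k, t = data.knot[i], data.time_idx[i]
        u, y, v = data.season_idx[i], data.year_idx[i], data.vessel_idx[i]
        expect_n = (params.beta_n[t] + params.omega_n[k] + params.xi_season_n[k, u]
                    + params.xi_year_n[k, y] + params.eps_n[k, t] + params.vessel_n[v])
        assert log_n[i] == pytest.approx(expect_n, rel=1e-14)
    # identical covariates give identical predictors
    data2 = _toy_data(b=[1.0, 1.0], a=[2, 2], knot=[1, 1], season=[0, 0],
                      year=[0, 0], vessel=[1, 1])
    ln2, lw2 = assemble_linear_predictors(params, data2)
    assert ln2[0] == ln2[1] and lw2[0] == lw2[1]


def test_all_random_effects_zero_reduces_to_intercept():
    params = _toy_params()
    params.beta_n = np.array([0.7, -0.2])
    data = _toy_data(b=[0, 1.0], a=[1, 1], knot=[0, 1], season=[0, 1],
                     year=[0, 0], vessel=[0, 1])
    log_n, _ = assemble_linear_predictors(params, data)
    np.testing.assert_allclose(log_n, params.beta_n[data.time_idx])


def test_zero_observation_contributes_minus_log_one_minus_p():
    # p = 0.5  <=>  a*n = log 2; the zero term is -log(1-p) = log 2
    val = data_negative_log_likelihood(
        b=np.array([0.0]), a=np.array([1.0]),
        log_n=np.array([np.log(np.log(2))]), log_w=np.array([0.0]),
        sigma_obs=0.5,
    )
    assert val == pytest.approx(-np.log(0.5), rel=1e-12)


def test_positive_at_median_matches_lognormal_density():
    a, n, w, sig = 2.0, 0.8, 30.0, 0.4
    p = encounter_prob(a, n)
    c = positive_rate(a, n, w)
    val = data_negative_log_likelihood(
        b=np.array([c]), a=np.array([a]), log_n=np.array([np.log(n)]),
        log_w=np.array([np.log(w)]), sigma_obs=sig,
    )
    # -log p - log lognormal_pdf(c; mu=log c, sigma)
    expect = -np.log(p) + np.log(c) + np.log(sig) + 0.5 * LOG_2PI
    assert val == pytest.approx(expect, rel=1e-12)


def test_duplicating_data_doubles_data_term_only():
    rng = np.random.default_rng(3)
    params = _toy_params(sigma_vessel_n=0.2, sigma_vessel_w=0.2)
    params.eps_n = rng.standard_normal(params.eps_n.shape) * 0.1
    params.vessel_n = np.array([0.05, -0.05])
    mesh = _toy_mesh()
    data = _toy_data(b=[0, 4.0, 1.5, 0], a=[1, 2, 1, 1], knot=[0, 1, 1, 0],
                     season=[0, 0, 1, 1], year=[0, 0, 0, 0], vessel=[0, 1, 0, 1])
    data2 = _toy_data(
        b=[0, 4.0, 1.5, 0] * 2, a=[1, 2, 1, 1] * 2, knot=[0, 1, 1, 0] * 2,
        season=[0, 0, 1, 1] * 2, year=[0] * 8, vessel=[0, 1, 0, 1] * 2,
    )
    nll1 = negative_log_likelihood(params, data, mesh)
    nll2 = negative_log_likelihood(params, data2, mesh)
    log_n, log_w = assemble_linear_predictors(params, data)
    data_term = data_negative_log_likelihood(
        data.b, data.a, log_n, log_w, params.sigma_obs
    )
    assert nll2 - nll1 == pytest.approx(data_term, rel=1e-10)


def test_nonzero_field_with_zero_sd_is_impossible():
    params = _toy_params(sigma_omega_n=0.0)
    params.omega_n = np.array([0.1, 0.0])
    mesh = _toy_mesh()
    data = _toy_data(b=[0, 1.0], a=[1, 1], knot=[0, 1], season=[0, 1],
                     year=[0, 0], vessel=[0, 1])
    assert negative_log_likelihood(params, data, mesh) == np.inf
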