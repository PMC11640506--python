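"""Laplace approximation against brute-force Gauss-Hermite integration.

On a two-knot, two-step toy model with fixed intercepts and only the
year-season random fields, the marginal likelihood can be computed by
adaptive tensor-product Gauss-Hermite quadrature over all eight random
effects.  The field SDs are kept small so the integrand sits inside the
Laplace regime: the comparison then isolates genuine implementation errors
(normalization constants, determinants, mode finding), which would show up
at the 0.1-1 log-unit scale, from the intrinsic asymptotic error of the
approximation itself.
"""

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss

from seastock.seasonal import LaplaceObjective, ModelData, SeasonalModelConfig
from seastock.spatial import KnotMesh

LOG_2PI = np.log(2 * np.pi)


def _toy_problem():
    coords = np.array([[0.0, 0.0], [120.0, 0.0]])
    mesh = KnotMesh(
        knots_lonlat=coords / 111.32, knots_km=coords,
        area_km2=np.array([40.0, 60.0]), origin=(0.0, 0.0), ref_lat=0.0,
    )
    rng = np.random.default_rng(7)
    n_obs = 120
    knot = rng.integers(0, 2, n_obs)
    season = rng.integers(0, 2, n_obs)
    a = rng.integers(1, 4, n_obs).astype(float)
    beta_n = np.array([-0.4, -0.1])
    beta_w = np.array([2.0, 2.3])
    n_lat = np.exp(beta_n[season] + 0.3 * rng.standard_normal(n_obs))
    p = 1 - np.exp(-a * n_lat)
    enc = rng.uniform(size=n_obs) < p
    w_lat = np.exp(beta_w[season])
    b = np.where(enc, a * n_lat * w_lat / np.clip(p, 1e-9, None)
                 * np.exp(0.3 * rng.standard_normal(n_obs)), 0.0)
    times = pd.DataFrame(
        {"t": [0, 1], "year": [2014, 2014], "year_idx": [0, 0],
         "season": ["s0", "s1"], "season_idx": [0, 1]}
    )
    data = ModelData(
        b=b, a=a, knot=knot, season_idx=season, year_idx=np.zeros(n_obs, dtype=int),
        time_idx=season, vessel_idx=np.zeros(n_obs, dtype=int), times=times,
        seasons=("s0", "s1"), years=np.array([2014]), vessels=np.array(["V1"]),
        n_knots=2,
    )
    config = SeasonalModelConfig(
        include_omega=False, include_season=False, include_year=False,
        include_epsilon=True, include_vessel=False,
    )
    obj = LaplaceObjective(data, mesh, config, beta_fixed=(beta_n, beta_w))
    theta = np.array(
        [np.log(0.07), np.log(0.06),  # sigma_eps n / w
         np.arctanh(-0.2), np.arctanh(0.3),  # rho n / w
         np.log(100.0), np.log(0.3)]  # range, sigma_obs
    )
    assert obj.theta_names == [
        "log_sigma_eps_n", "log_sigma_eps_w", "atanh_rho_n", "atanh_rho_w",
        "log_range", "log_sigma_obs",
    ]
    assert obj.dim_u == 8
    return obj, theta


def _dense_design(obj):
    zn = np.zeros((obj.data.n_obs, obj.dim_u))
    zw = np.zeros_like(zn)
    rows = np.arange(obj.data.n_obs)[:, None]
    np.add.at(zn, (rows, obj.cols_n), 1.0)
    np.add.at(zw, (rows, obj.cols_w), 1.0)
    return zn, zw


def _joint_f_batch(obj, theta, priors, uc, design):
    """Vectorized data NLL + quadratic prior over a batch of effect vectors."""
    td = obj.theta_dict(theta)
    sigma = float(np.exp(td["log_sigma_obs"]))
    d = obj.data
    zn, zw = design
    eta = uc @ zn.T + obj.off_n[None, :]
    zeta = uc @ zw.T + obj.off_w[None, :]
    an = d.a[None, :] * np.exp(eta)
    zero = obj.zero_mask
    val = an[:, zero].sum(axis=1)
    anp = an[:, obj.pos_mask]
    p = -np.expm1(-anp)
    log_c = obj.log_a_pos[None, :] + eta[:, obj.pos_mask] + zeta[:, obj.pos_mask] - np.log(p)
    dres = (obj.log_b_pos[None, :] - log_c) / sigma
    val += (-np.log(p) + 0.5 * dres**2).sum(axis=1)
    val += obj.pos_mask.sum() * (np.log(sigma) + 0.5 * LOG_2PI) + obj.log_b_pos.sum()
    q_full = np.zeros((obj.dim_u, obj.dim_u))
    for bl, q, _ in priors:
        q_full[bl.sl, bl.sl] = q
    val += 0.5 * np.einsum("mi,ij,mj->m", uc, q_full, uc)
    return val


def _quadrature_nll(obj, theta, n_nodes):
    """Adaptive tensor GH evaluation of the exact marginal NLL."""
    value_lap, u_hat, h = obj.marginal_nll(theta)
    priors = obj.prior_blocks(theta)
    logdet_q = sum(ld for _, _, ld in priors)
    dim = obj.dim_u
    # scale the grid by the curvature at the mode
    chol = np.linalg.cholesky(h)
    c = np.linalg.inv(chol).T  # u = u_hat + c @ z has unit curvature
    nodes, weights = hermegauss(n_nodes)
    grids = np.meshgrid(*([nodes] * dim), indexing="ij")
    z = np.column_stack([g.ravel() for g in grids])
    log_w = np.log(np.meshgrid(*([weights] * dim), indexing="ij"))
    log_wk = sum(lw.ravel() for lw in log_w)

    design = _dense_design(obj)
    f0 = float(_joint_f_batch(obj, theta, priors, u_hat[None, :], design)[0])
    log_terms = np.empty(z.shape[0])
    for start in range(0, z.shape[0], 50000):
        zc = z[start:start + 50000]
        uc = u_hat[None, :] + zc @ c.T
        fs = _joint_f_batch(obj, theta, priors, uc, design)
        log_terms[start:start + 50000] = -(fs - f0) + 0.5 * (zc**2).sum(axis=1)
    shifted = log_terms + log_wk
    log_i = (
        np.log(np.sum(np.exp(shifted - shifted.max()))) + shifted.max()
        + np.log(np.abs(np.linalg.det(c)))
        - f0
    )
    # -log ML = -log integral + (n/2) log 2pi - 0.5 logdet Q
    return -(log_i) + 0.5 * dim * LOG_2PI - 0.5 * logdet_q, value_lap


def test_laplace_matches_gauss_hermite_quadrature():
    obj, theta = _toy_problem()
    nll_q4, nll_lap = _quadrature_nll(obj, theta, 4)
    nll_q6, _ = _quadrature_nll(obj, theta, 6)
    # quadrature is internally converged ...
    assert abs(nll_q6 - nll_q4) < 5e-4
    # ... and the Laplace approximation agrees with it
    assert abs(nll_lap - nll_q6) < 1e-3


def test_laplace_exact_for_shifted_parameters():
    # agreement is not an artifact of one parameter point
    obj, theta = _toy_problem()
    theta2 = theta + np.array([0.1, -0.1, 0.5, -0.4, 0.2, -0.1])
    nll_q, nll_lap = _quadrature_nll(obj, theta2, 6)
    assert abs(nll_lap - nll_q) < 1e-3
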