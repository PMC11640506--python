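"""Conventional model-based CPUE standardization (the benchmark model).

An additive model on log CPUE with Year and Month as factors, smooth
(B-spline) terms for longitude, latitude and vessel length, and the six
pairwise spatio-temporal interactions (Year x Month, Year x Longitude,
Year x Latitude, Month x Longitude, Month x Latitude, Longitude x
Latitude) as factor-smooth or tensor-product terms.  The annual index is
the back-transformed prediction averaged over a balanced reference grid
(all months x a spatial lattice x the median vessel length), so the index
is not confounded by where the fleet chose to fish.

This benchmark deliberately retains the known weaknesses of conventional
standardization (log-only response, sensitivity to effort allocation and
outlier cells); it exists to be compared against, not to be fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix

ALL_INTERACTIONS = (
    "year_month",
    "year_lon",
    "year_lat",
    "month_lon",
    "month_lat",
    "lon_lat",
)


@dataclass
class ConventionalConfig:
    df_space: int = 6
    df_vessel: int = 4
    df_interaction: int = 3
    interactions: tuple[str, ...] = ALL_INTERACTIONS
    ridge: float = 1e-4  # small L2 on non-main-effect columns
    bias_correct: bool = True

    def formula(self) -> str:
        di = self.df_interaction
        parts = [
            "C(year)",
            "C(month)",
            f"bs(lon, df={self.df_space})",
            f"bs(lat, df={self.df_space})",
            f"bs(vessel_length_m, df={self.df_vessel})",
        ]
        inter_map = {
            "year_month": "C(year):C(month)",
            "year_lon": f"C(year):bs(lon, df={di})",
            "year_lat": f"C(year):bs(lat, df={di})",
            "month_lon": f"C(month):bs(lon, df={di})",
            "month_lat": f"C(month):bs(lat, df={di})",
            "lon_lat": f"bs(lon, df={di}):bs(lat, df={di})",
        }
        for key in self.interactions:
            parts.append(inter_map[key])
        return " + ".join(parts)


@dataclass
class ConventionalFit:
    """Stored coefficients and design information of the benchmark model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float  # residual variance on the log scale
    design_info: object
    config: ConventionalConfig
    n: int
    n_dropped: int
    deviance_explained: float
    deficient_terms: list[str]
    years: np.ndarray
    months: np.ndarray
    lon_range: tuple[float, float]
    lat_range: tuple[float, float]
    median_vessel_length: float

    def year_effects(self) -> pd.DataFrame:
        """Year factor contrasts (vs the first year) with standard errors."""
        names = self.design_info.column_names
        rows = []
        for j, name in enumerate(names):
            if name.startswith("C(year)[T.") and "]" in name and ":" not in name:
                year = name[len("C(year)[T."):-1]
                rows.append(
                    {"year": int(float(year)), "effect": self.beta[j],
                     "se": float(np.sqrt(self.cov_beta[j, j]))}
                )
        return pd.DataFrame(rows)


def _prepare_frame(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    cpue = records["catch_kg"].to_numpy(dtype=float) / records[
        "effort_days"
    ].to_numpy(dtype=float)
    keep = cpue > 0
    n_dropped = int((~keep).sum())
    df = pd.DataFrame(
        {
            "log_cpue": np.log(cpue[keep]),
            "year": records["year"].to_numpy()[keep],
            "month": records["month"].to_numpy()[keep],
            "lon": records["lon"].to_numpy(dtype=float)[keep],
            "lat": records["lat"].to_numpy(dtype=float)[keep],
            "vessel_length_m": records["vessel_length_m"].to_numpy(dtype=float)[keep],
        }
    )
    return df, n_dropped


def fit_conventional(
    records: pd.DataFrame, config: ConventionalConfig | None = None
) -> ConventionalFit:
    """Ridge-stabilized additive fit of log CPUE (zero-CPUE rows dropped)."""
    config = config or ConventionalConfig()
    df, n_dropped = _prepare_frame(records)
    if df.empty:
        raise ValueError("no positive-CPUE records to fit")
    for term in ("year", "month"):
        if df[term].nunique() < 2:
            raise ValueError(
                f"term '{term.capitalize()}' has fewer than 2 levels; "
                "the factor is not estimable"
            )
    x = dmatrix(config.formula(), df, return_type="matrix")
    design_info = x.design_info
    x = np.asarray(x)
    y = df["log_cpue"].to_numpy()
    n, p = x.shape

    # penalize everything except intercept and main factor levels
    pen = np.ones(p) * config.ridge
    for term, sl in design_info.term_name_slices.items():
        if ":" not in term:
            pen[sl] = config.ridge * 1e-2
    pen[0] = 0.0

    deficient = []
    for term, sl in design_info.term_name_slices.items():
        sub = x[:, sl]
        if sub.shape[1] and np.linalg.matrix_rank(sub) < sub.shape[1]:
            deficient.append(term)

    xtx = x.T @ x
    xty = x.T @ y
    a = xtx + np.diag(pen * max(1.0, np.trace(xtx) / p))
    beta = np.linalg.solve(a, xty)
    resid = y - x @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    a_inv = np.linalg.inv(a)
    cov_beta = sigma2 * (a_inv @ xtx @ a_inv)
    tss = float(((y - y.mean()) ** 2).sum())
    dev_expl = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan

    return ConventionalFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=sigma2,
        design_info=design_info,
        config=config,
        n=n,
        n_dropped=n_dropped,
        deviance_explained=dev_expl,
        deficient_terms=deficient,
        years=np.sort(df["year"].unique()),
        months=np.sort(df["month"].unique()),
        lon_range=(float(df["lon"].min()), float(df["lon"].max())),
        lat_range=(float(df["lat"].min()), float(df["lat"].max())),
        median_vessel_length=float(df["vessel_length_m"].median()),
    )


def make_prediction_grid(fit: ConventionalFit, n_space: int = 8) -> pd.DataFrame:
    """Balanced reference grid: years x months x spatial lattice x median vessel."""
    lons = np.linspace(*fit.lon_range, n_space)
    lats = np.linspace(*fit.lat_range, n_space)
    grids = np.array(
        np.meshgrid(fit.years, fit.months, lons, lats)
    ).reshape(4, -1).T
    return pd.DataFrame(
        {
            "year": grids[:, 0].astype(int),
            "month": grids[:, 1].astype(int),
            "lon": grids[:, 2],
            "lat": grids[:, 3],
            "vessel_length_m": fit.median_vessel_length,
        }
    )


def predict_annual_index(
    fit: ConventionalFit,
    prediction_grid: pd.DataFrame | None = None,
    n_draws: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Annual standardized index from balanced-grid prediction.

    Predictions are back-transformed with the half-variance log-normal
    correction exp(sigma^2/2) (config toggle) and averaged within year;
    standard errors come from simulating the coefficient vector.
    """
    if prediction_grid is None:
        prediction_grid = make_prediction_grid(fit)
    if prediction_grid.empty:
        raise ValueError("empty prediction grid")
    out_lon = (prediction_grid["lon"] < fit.lon_range[0]) | (
        prediction_grid["lon"] > fit.lon_range[1]
    )
    out_lat = (prediction_grid["lat"] < fit.lat_range[0]) | (
        prediction_grid["lat"] > fit.lat_range[1]
    )
    if (out_lon | out_lat).any():
        warnings.warn(
            f"{int((out_lon | out_lat).sum())} prediction points fall outside "
            "the observed spatial hull; they are clipped to its boundary "
            "(the spline basis is undefined beyond its outer knots)",
            stacklevel=2,
        )
        prediction_grid = prediction_grid.copy()
        prediction_grid["lon"] = prediction_grid["lon"].clip(*fit.lon_range)
        prediction_grid["lat"] = prediction_grid["lat"].clip(*fit.lat_range)
    (x_pred,) = build_design_matrices([fit.design_info], prediction_grid)
    x_pred = np.asarray(x_pred)
    correction = 0.5 * fit.sigma2 if fit.config.bias_correct else 0.0
    years = prediction_grid["year"].to_numpy()

    def annual_mean(beta: np.ndarray) -> pd.Series:
        pred = np.exp(x_pred @ beta + correction)
        return pd.Series(pred).groupby(years).mean()

    point = annual_mean(fit.beta)
    rng = np.random.default_rng(seed)
    cov = 0.5 * (fit.cov_beta + fit.cov_beta.T)
    w_eig, v_eig = np.linalg.eigh(cov)
    factor = v_eig * np.sqrt(np.clip(w_eig, 0.0, None))
    draws = fit.beta[:, None] + factor @ rng.standard_normal((len(fit.beta), n_draws))
    sim = np.column_stack([annual_mean(draws[:, j]).to_numpy() for j in range(n_draws)])
    se = sim.std(axis=1, ddof=1)
    return pd.DataFrame(
        {
            "year": point.index.to_numpy().astype(int),
            "index": point.to_numpy(),
            "se": se,
            "cv": se / point.to_numpy(),
        }
    )
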