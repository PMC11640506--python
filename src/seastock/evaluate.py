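"""Comparison machinery: relative errors, Mann-Kendall trends and
cross-validation of an abundance index through the assessment model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .amsy import AMSYPriors, ProcessErrorConfig, filter_viable, sample_rkq


def relative_error(predicted, observed):
    """RE = (pred - obs) / obs."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if np.any(observed == 0):
        raise ValueError("relative error undefined for observed = 0")
    return (predicted - observed) / observed


def average_abs_relative_error(re_series) -> float:
    """ARE: mean of |RE| over the years of the series."""
    re_series = np.asarray(re_series, dtype=float)
    if re_series.size == 0:
        raise ValueError("empty RE series")
    return float(np.mean(np.abs(re_series)))


@dataclass
class TrendTestResult:
    """Mann-Kendall monotone-trend test (two-sided, tie-corrected)."""

    tau: float
    s: int
    p_value: float
    n: int


def mann_kendall(series) -> TrendTestResult:
    """Non-parametric trend test: S = sum of sign(x_j - x_i) over i < j.

    tau is the tie-corrected (tau-b) rank correlation with time; the
    p-value uses the tie-corrected normal approximation with continuity
    correction.  A constant series returns tau = 0, p = 1 by convention.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Mann-Kendall test needs at least 3 observations")
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, 1).sum())

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    n_pairs = n * (n - 1) / 2
    tie_pairs = float((ties * (ties - 1) / 2).sum())
    denom = np.sqrt((n_pairs - tie_pairs) * n_pairs)
    if denom == 0:
        return TrendTestResult(tau=0.0, s=s, p_value=1.0, n=n)
    tau = s / denom

    var_s = (
        n * (n - 1) * (2 * n + 5) - float((ties * (ties - 1) * (2 * ties + 5)).sum())
    ) / 18.0
    if var_s <= 0:
        return TrendTestResult(tau=0.0, s=s, p_value=1.0, n=n)
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = float(min(1.0, 2.0 * (1.0 - norm.cdf(abs(z)))))
    return TrendTestResult(tau=float(tau), s=s, p_value=max(p, np.finfo(float).tiny), n=n)


@dataclass
class CrossValReport:
    """Fitted-vs-observed index comparison through the assessment model."""

    table: pd.DataFrame  # year, observed, fitted, re
    are: float
    re_lo95: float
    re_hi95: float
    scheme: str

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "are": self.are,
            "re_lo95": self.re_lo95,
            "re_hi95": self.re_hi95,
        }


def _viable_pairs(index, priors_template, n_samples, error_config, seed):
    priors = AMSYPriors(
        index=index,
        r_range=priors_template.r_range,
        bk_prior=priors_template.bk_prior,
        anchor_year=priors_template.anchor_year
        if priors_template.anchor_year in set(index["year"])
        else int(index["year"].min()),
        log_corr=priors_template.log_corr,
    )
    ens = sample_rkq(priors, n_samples=n_samples, seed=seed)
    ens = filter_viable(ens, priors.index, priors, error_config)
    return ens.r[ens.viable], ens.kq[ens.viable]


def _median_dynamics_prediction(a, r, kq):
    """In-sample fitted index: forward Schaefer run per viable pair.

    Catches are the pair's own implied catches from the observed series;
    the trajectory starts at the observed first year, so deviations
    accumulate where the pair's production disagrees with the data.
    """
    m, n_t = r.size, a.size
    cq = a[None, :-1] + a[None, :-1] * r[:, None] * (1 - a[None, :-1] / kq[:, None]) - a[None, 1:]
    cq_med = np.median(cq, axis=0)  # one catch series for all pairs
    traj = np.empty((m, n_t))
    traj[:, 0] = a[0]
    for t in range(n_t - 1):
        prod = traj[:, t] * r * (1 - traj[:, t] / kq)
        traj[:, t + 1] = np.maximum(traj[:, t] + prod - cq_med[t], 1e-12)
    return np.median(traj, axis=0)


def cross_validate(
    index: pd.DataFrame,
    priors: AMSYPriors | None = None,
    scheme: str = "loo",
    n_samples: int = 5000,
    error_config: ProcessErrorConfig | None = None,
    seed: int = 0,
) -> CrossValReport:
    """Fitted-vs-observed comparison of an index through AMSY.

    scheme="loo": for each year past the first, drop it, re-filter the
    viable cloud on the remaining years, and predict the held-out value by
    one Schaefer step from its predecessor, with the held-out catch
    approximated by the most recent observed exploitation rate.
    scheme="insample": fit once and compare the median forward trajectory
    with the observed series.
    """
    idx = index.sort_values("year").reset_index(drop=True)
    if len(idx) < 4:
        raise ValueError("cross-validation needs at least 4 years of index")
    if priors is None:
        priors = AMSYPriors(index=idx)
    a = idx["index"].to_numpy(dtype=float)
    years = idx["year"].to_numpy()

    if scheme == "insample":
        r, kq = _viable_pairs(idx, priors, n_samples, error_config, seed)
        fitted = _median_dynamics_prediction(a, r, kq)
        rows = pd.DataFrame({"year": years, "observed": a, "fitted": fitted})
    elif scheme == "loo":
        rows_list = []
        for i in range(1, len(idx)):
            reduced = idx.drop(index=i).reset_index(drop=True)
            r, kq = _viable_pairs(reduced, priors, n_samples, error_config, seed + i)
            a_prev = a[i - 1]
            # exploitation rate from the most recent step fully observed
            if i >= 2:
                cq_prev = (
                    a[i - 2] + a[i - 2] * r * (1 - a[i - 2] / kq) - a_prev
                )
                u_rate = np.clip(cq_prev / a[i - 2], 0.0, None)
            else:
                u_rate = np.zeros_like(r)
            pred = a_prev + a_prev * r * (1 - a_prev / kq) - u_rate * a_prev
            rows_list.append(
                {"year": int(years[i]), "observed": a[i], "fitted": float(np.median(pred))}
            )
        rows = pd.DataFrame(rows_list)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rows["re"] = relative_error(rows["fitted"], rows["observed"])
    re = rows["re"].to_numpy()
    return CrossValReport(
        table=rows,
        are=average_abs_relative_error(re),
        re_lo95=float(np.percentile(re, 2.5)),
        re_hi95=float(np.percentile(re, 97.5)),
        scheme=scheme,
    )
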