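"""Data-limited surplus-production assessment from an abundance index.

Works entirely in catchability-scaled (relative) units: with index
``A_t = B_t * q``, the Schaefer dynamics imply a relative catch

    Cq_t = A_t + A_t * r * (1 - A_t / K_q) - A_{t+1}

for each pair of consecutive index values.  Candidate (r, K_q) pairs are
drawn from a multivariate log-normal matched to a uniform-like prior on r
and a relative-biomass (B/K) prior anchored at one year; pairs are kept
("viable") only if, in at least one of several error-perturbed trials, all
implied catches are non-negative and the anchor-year B/K falls inside its
prior window.  Reference points follow the Schaefer identities
MSY_q = r*K_q/4, F_MSY = r/2, B_MSY_q = K_q/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KOBE_REGIONS = ("green", "orange", "yellow", "red")


@dataclass
class AMSYPriors:
    """Priors and the index they apply to.

    r_range : uniform-like prior range for the intrinsic growth rate
        (default 0.6-1.5, the high-resilience small-pelagic setting).
    bk_prior : (low, high) window for relative biomass B/K at ``anchor_year``
        ("about half" maps to (0.4, 0.6)).
    index : frame with columns year, index (the abundance series A_t).
    log_corr : correlation of log r and log K_q in the sampling distribution.
    """

    index: pd.DataFrame
    r_range: tuple[float, float] = (0.6, 1.5)
    bk_prior: tuple[float, float] = (0.4, 0.6)
    anchor_year: int | None = None
    log_corr: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.r_range
        if not (0 < lo < hi):
            raise ValueError("r prior requires 0 < low < high")
        blo, bhi = self.bk_prior
        if not (0 < blo < bhi <= 1):
            raise ValueError("B/K prior requires 0 < low < high <= 1")
        self.index = self.index.sort_values("year").reset_index(drop=True)
        if (self.index["index"] <= 0).any():
            raise ValueError("abundance index values must be positive")
        years = self.index["year"].to_numpy()
        if self.anchor_year is None:
            self.anchor_year = int(years[0])
        if self.anchor_year not in years:
            raise ValueError(f"anchor year {self.anchor_year} not in index span")
        if not abs(self.log_corr) < 1:
            raise ValueError("log_corr must lie in (-1, 1)")

    @property
    def a(self) -> np.ndarray:
        return self.index["index"].to_numpy(dtype=float)

    @property
    def anchor_pos(self) -> int:
        return int(np.flatnonzero(self.index["year"].to_numpy() == self.anchor_year)[0])


@dataclass
class ProcessErrorConfig:
    """Error settings for the viability filter trials."""

    n_trials: int = 10
    process_cv: float = 0.1
    observation_cv: float = 0.1


@dataclass
class RKqEnsemble:
    """Sampled (r, K_q) pairs with viability flags."""

    r: np.ndarray
    kq: np.ndarray
    viable: np.ndarray  # bool, all False until filtered
    seed: int

    @property
    def n_tested(self) -> int:
        return self.r.size

    @property
    def n_viable(self) -> int:
        return int(self.viable.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "kq": self.kq, "viable": self.viable})


def surplus_production_step(a_t, r, k_q, a_next):
    """Relative catch implied by Schaefer dynamics between two index values."""
    a_t = np.asarray(a_t, dtype=float)
    if np.any(a_t <= 0) or np.any(np.asarray(k_q, dtype=float) <= 0):
        raise ValueError("index values and K_q must be positive")
    return a_t + a_t * r * (1.0 - a_t / k_q) - a_next


def _range_to_lognormal(lo: float, hi: float) -> tuple[float, float]:
    """Moment-match a (midpoint, quarter-range) spread to log scale."""
    mean = 0.5 * (lo + hi)
    sd = 0.25 * (hi - lo)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, np.sqrt(sigma2)


def sample_rkq(priors: AMSYPriors, n_samples: int = 30_000, seed: int = 0) -> RKqEnsemble:
    """Draw tested (r, K_q) pairs from a multivariate log-normal.

    log r and log K_q are jointly normal; the r marginal matches the
    uniform-like prior range, the K_q marginal is centred at
    A_anchor / midpoint(B/K prior) with spread from the window edges.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mu_r, sd_r = _range_to_lognormal(*priors.r_range)
    a_anchor = priors.a[priors.anchor_pos]
    blo, bhi = priors.bk_prior
    mu_k, sd_k = _range_to_lognormal(a_anchor / bhi, a_anchor / blo)
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [sd_r**2, priors.log_corr * sd_r * sd_k],
            [priors.log_corr * sd_r * sd_k, sd_k**2],
        ]
    )
    z = rng.multivariate_normal([mu_r, mu_k], cov, size=n_samples, method="cholesky")
    return RKqEnsemble(
        r=np.exp(z[:, 0]), kq=np.exp(z[:, 1]),
        viable=np.zeros(n_samples, dtype=bool), seed=seed,
    )


def filter_viable(
    ensemble: RKqEnsemble,
    index: pd.DataFrame,
    priors: AMSYPriors,
    error_config: ProcessErrorConfig | None = None,
    seed: int | None = None,
) -> RKqEnsemble:
    """Flag pairs whose implied catch series can be non-negative.

    Each pair is tried ``n_trials`` times with multiplicative log-normal
    observation error on the index and process error on surplus production;
    it is viable iff at least one trial gives Cq_t >= 0 for every step and
    an anchor-year B/K inside the prior window.
    """
    ec = error_config or ProcessErrorConfig()
    a = index.sort_values("year")["index"].to_numpy(dtype=float)
    if a.size < 2:
        raise ValueError("index must cover at least two years")
    rng = np.random.default_rng(ensemble.seed + 1 if seed is None else seed)
    m = ensemble.n_tested
    n_t = a.size
    r = ensemble.r[:, None, None]
    kq = ensemble.kq[:, None, None]
    # observation error: one perturbed index per (pair, trial)
    obs = a[None, None, :] * np.exp(
        ec.observation_cv * rng.standard_normal((m, ec.n_trials, n_t))
    )
    proc = np.exp(ec.process_cv * rng.standard_normal((m, ec.n_trials, n_t - 1)))
    a_t = obs[:, :, :-1]
    cq = a_t + a_t * r * (1.0 - a_t / kq) * proc - obs[:, :, 1:]
    bk_anchor = obs[:, :, priors.anchor_pos] / ensemble.kq[:, None]
    blo, bhi = priors.bk_prior
    ok = (cq >= 0).all(axis=2) & (bk_anchor >= blo) & (bk_anchor <= bhi)
    viable = ok.any(axis=1)
    if not viable.any():
        raise RuntimeError(
            "no viable r-K_q pairs: every sampled combination produced negative "
            "catches or violated the B/K anchor window; widen the priors"
        )
    return RKqEnsemble(r=ensemble.r, kq=ensemble.kq, viable=viable, seed=ensemble.seed)


def kobe_classify(f_ratio: float, b_ratio: float) -> str:
    """Kobe quadrant; boundaries resolve toward the safer region.

    green: B/B_MSY >= 1 and F/F_MSY <= 1 (sustainable);
    yellow: B >= 1 with overfishing; orange: depleted but F under control;
    red: depleted and overfishing.
    """
    if f_ratio < 0 or b_ratio < 0:
        raise ValueError("ratios must be non-negative")
    if b_ratio >= 1.0:
        return "green" if f_ratio <= 1.0 else "yellow"
    return "orange" if f_ratio <= 1.0 else "red"


@dataclass
class AssessmentResult:
    """Per-year relative quantities with 95% intervals and stock status."""

    table: pd.DataFrame  # year, cq/f_fmsy/b_bmsy medians and 95% bounds, kobe
    msy_q: float
    msy_q_lo: float
    msy_q_hi: float
    status_probs: dict[str, float]
    status_year: int
    recruitment_impaired: bool
    n_viable: int

    def to_dict(self) -> dict:
        return {
            "msy_q": self.msy_q,
            "msy_q_lo95": self.msy_q_lo,
            "msy_q_hi95": self.msy_q_hi,
            "status_probs": self.status_probs,
            "status_year": self.status_year,
            "recruitment_impaired": bool(self.recruitment_impaired),
            "n_viable": self.n_viable,
            "years": self.table.to_dict(orient="records"),
        }


def _quantiles(x: np.ndarray, axis=0):
    return (
        np.median(x, axis=axis),
        np.percentile(x, 2.5, axis=axis),
        np.percentile(x, 97.5, axis=axis),
    )


def reference_points(
    ensemble: RKqEnsemble, index: pd.DataFrame, priors: AMSYPriors | None = None
) -> AssessmentResult:
    """Schaefer reference points across the viable cloud.

    Per viable pair and year: F/F_MSY = 2*Cq_t/(r*A_t), B/B_MSY = 2*A_t/K_q,
    MSY_q = r*K_q/4.  Catches exist for all but the final year; the
    final-year status combines final-year B/B_MSY with the last available
    F/F_MSY.  Status probabilities are viable-pair fractions per Kobe
    region in that final state.
    """
    if ensemble.n_viable == 0:
        raise RuntimeError("no viable pairs to compute reference points from")
    idx = index.sort_values("year").reset_index(drop=True)
    years = idx["year"].to_numpy()
    a = idx["index"].to_numpy(dtype=float)
    r = ensemble.r[ensemble.viable][:, None]
    kq = ensemble.kq[ensemble.viable][:, None]

    cq = a[None, :-1] + a[None, :-1] * r * (1.0 - a[None, :-1] / kq) - a[None, 1:]
    f_fmsy = 2.0 * cq / (r * a[None, :-1])
    b_bmsy = 2.0 * a[None, :] / kq
    msy = (r * kq / 4.0)[:, 0]

    cq_med, cq_lo, cq_hi = _quantiles(cq)
    f_med, f_lo, f_hi = _quantiles(f_fmsy)
    b_med, b_lo, b_hi = _quantiles(b_bmsy)
    msy_med, msy_lo, msy_hi = _quantiles(msy)

    rows = []
    for i, year in enumerate(years):
        has_cq = i < len(years) - 1
        f_for_kobe = f_med[i] if has_cq else f_med[-1]
        rows.append(
            {
                "year": int(year),
                "cq_med": cq_med[i] if has_cq else np.nan,
                "cq_lo95": cq_lo[i] if has_cq else np.nan,
                "cq_hi95": cq_hi[i] if has_cq else np.nan,
                "f_fmsy_med": f_med[i] if has_cq else np.nan,
                "f_fmsy_lo95": f_lo[i] if has_cq else np.nan,
                "f_fmsy_hi95": f_hi[i] if has_cq else np.nan,
                "b_bmsy_med": b_med[i],
                "b_bmsy_lo95": b_lo[i],
                "b_bmsy_hi95": b_hi[i],
                "kobe": kobe_classify(max(f_for_kobe, 0.0), b_med[i]),
            }
        )
    table = pd.DataFrame(rows)

    f_final = np.maximum(f_fmsy[:, -1], 0.0)
    b_final = b_bmsy[:, -1]
    labels = np.where(
        b_final >= 1.0,
        np.where(f_final <= 1.0, "green", "yellow"),
        np.where(f_final <= 1.0, "orange", "red"),
    )
    n_v = ensemble.n_viable
    status = {reg: float((labels == reg).sum()) / n_v for reg in KOBE_REGIONS}
    return AssessmentResult(
        table=table,
        msy_q=float(msy_med), msy_q_lo=float(msy_lo), msy_q_hi=float(msy_hi),
        status_probs=status,
        status_year=int(years[-1]),
        recruitment_impaired=bool(b_med[-1] < 0.5),
        n_viable=n_v,
    )


def assess(
    index: pd.DataFrame,
    priors: AMSYPriors | None = None,
    n_samples: int = 30_000,
    error_config: ProcessErrorConfig | None = None,
    seed: int = 0,
) -> tuple[AssessmentResult, RKqEnsemble]:
    """Full AMSY run: sample, filter, reference points."""
    if priors is None:
        priors = AMSYPriors(index=index)
    ensemble = sample_rkq(priors, n_samples=n_samples, seed=seed)
    ensemble = filter_viable(ensemble, priors.index, priors, error_config)
    return reference_points(ensemble, priors.index, priors), ensemble


def mean_seasonal_index(
    spring: pd.DataFrame, summer: pd.DataFrame, autumn: pd.DataFrame
) -> pd.DataFrame:
    """Per-year arithmetic mean of the three seasonal indices."""
    frames = {"spring": spring, "summer": summer, "autumn": autumn}
    years = None
    for name, df in frames.items():
        ys = set(int(y) for y in df["year"])
        if years is None:
            years = ys
        elif ys != years:
            missing = sorted(years.symmetric_difference(ys))
            raise ValueError(
                f"season '{name}' does not share the common year span; "
                f"mismatched years: {missing}"
            )
    merged = None
    for name, df in frames.items():
        part = df[["year", "index"]].rename(columns={"index": name})
        merged = part if merged is None else merged.merge(part, on="year")
    merged = merged.sort_values("year").reset_index(drop=True)
    out = merged[["year"]].copy()
    out["index"] = merged[["spring", "summer", "autumn"]].mean(axis=1)
    return out
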