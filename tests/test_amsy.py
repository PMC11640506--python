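"""Schaefer identities, prior sampling, viability filtering, Kobe status."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seastock.amsy import (
    AMSYPriors,
    ProcessErrorConfig,
    RKqEnsemble,
    assess,
    filter_viable,
    kobe_classify,
    mean_seasonal_index,
    reference_points,
    sample_rkq,
)
from _oracles import schaefer_index


def test_surplus_production_closed_forms():
    from seastock.amsy import surplus_production_step

    # no production and no change at carrying capacity
    assert surplus_production_step(4.0, 0.8, 4.0, 4.0) == 0.0
    # at half of K_q a stationary index yields MSY_q = r*K_q/4
    r, kq = 0.9, 10.0
    assert surplus_production_step(kq / 2, r, kq, kq / 2) == pytest.approx(r * kq / 4)
    assert surplus_production_step(2.0, 1.0, 4.0, 1.5) == pytest.approx(1.5)


@settings(max_examples=100, deadline=None)
@given(
    r=st.floats(min_value=0.1, max_value=2.0),
    kq=st.floats(min_value=1.0, max_value=1e4),
)
def test_msy_identity(r, kq):
    from seastock.amsy import surplus_production_step

    assert surplus_production_step(kq / 2, r, kq, kq / 2) == pytest.approx(
        r * kq / 4, rel=1e-12
    )


@pytest.fixture
def flat_index():
    return pd.DataFrame({"year": np.arange(2014, 2023), "index": np.full(9, 500.0)})


def test_sampler_deterministic_and_independent(flat_index):
    priors = AMSYPriors(index=flat_index)
    e1 = sample_rkq(priors, n_samples=20_000, seed=5)
    e2 = sample_rkq(priors, n_samples=20_000, seed=5)
    np.testing.assert_array_equal(e1.r, e2.r)
    corr = np.corrcoef(np.log(e1.r), np.log(e1.kq))[0, 1]
    assert abs(corr) < 3 / np.sqrt(e1.n_tested)


def test_sampler_marginal_covers_prior_range(flat_index):
    priors = AMSYPriors(index=flat_index)
    ens = sample_rkq(priors, n_samples=50_000, seed=2)
    inside = np.mean((ens.r > 0.6) & (ens.r < 1.5))
    assert 0.90 < inside < 0.985
    # K_q centred at A_anchor / midpoint(B/K)
    assert np.median(ens.kq) == pytest.approx(500.0 / 0.5, rel=0.05)
    with pytest.raises(ValueError):
        sample_rkq(priors, n_samples=0)


def test_generating_pair_is_viable_on_noise_free_index():
    r_true, kq_true = 1.0, 1000.0
    idx = schaefer_index(r_true, kq_true, 500.0, [100.0] * 8)
    priors = AMSYPriors(index=idx, bk_prior=(0.4, 0.6))
    ens = RKqEnsemble(
        r=np.array([r_true]), kq=np.array([kq_true]),
        viable=np.zeros(1, dtype=bool), seed=0,
    )
    out = filter_viable(ens, idx, priors, ProcessErrorConfig(n_trials=10))
    assert out.viable[0]


def test_kq_below_index_maximum_is_rejected():
    idx = schaefer_index(0.8, 1000.0, 500.0, [50.0] * 8)  # rising index
    priors = AMSYPriors(index=idx, bk_prior=(0.05, 1.0))
    ens = RKqEnsemble(
        r=np.array([0.8]), kq=np.array([0.9 * idx["index"].max()]),
        viable=np.zeros(1, dtype=bool), seed=0,
    )
    with pytest.raises(RuntimeError, match="no viable"):
        filter_viable(ens, idx, priors, ProcessErrorConfig(n_trials=10))


def test_tight_wrong_anchor_window_reduces_viability():
    idx = schaefer_index(1.0, 1000.0, 500.0, [150.0] * 8)
    base = sample_rkq(AMSYPriors(index=idx), n_samples=4000, seed=3)
    frac = {}
    for window in [(0.4, 0.6), (0.9, 1.0)]:
        priors = AMSYPriors(index=idx, bk_prior=window)
        try:
            out = filter_viable(base, idx, priors, seed=11)
            frac[window] = out.n_viable
        except RuntimeError:
            frac[window] = 0
    assert frac[(0.9, 1.0)] < frac[(0.4, 0.6)]


def test_reference_point_identities():
    r, kq = 1.2, 800.0
    # stationary at K_q/2: B/B_MSY = 1 and Cq = r*A/2 exactly, so F/F_MSY = 1
    idx = pd.DataFrame({"year": [2014, 2015, 2016], "index": [kq / 2] * 3})
    ens = RKqEnsemble(
        r=np.array([r]), kq=np.array([kq]), viable=np.ones(1, dtype=bool), seed=0
    )
    res = reference_points(ens, idx)
    assert res.table["b_bmsy_med"].to_numpy() == pytest.approx([1.0, 1.0, 1.0])
    assert res.table["f_fmsy_med"].to_numpy()[:-1] == pytest.approx([1.0, 1.0])
    assert res.msy_q == pytest.approx(r * kq / 4)
    # Cq = (F/F_MSY) * (r/2) * A reproduces the production equation exactly
    cq = res.table["cq_med"].to_numpy()[:-1]
    f = res.table["f_fmsy_med"].to_numpy()[:-1]
    np.testing.assert_allclose(cq, f * (r / 2) * (kq / 2), rtol=1e-14)


@pytest.mark.parametrize(
    "f,b,region",
    [(0.5, 1.5, "green"), (1.5, 0.5, "red"), (1.5, 1.5, "yellow"),
     (0.5, 0.5, "orange"), (1.0, 1.0, "green"), (1.0, 0.99, "orange")],
)
def test_kobe_quadrants_and_boundaries(f, b, region):
    assert kobe_classify(f, b) == region


def test_kobe_rejects_negative():
    with pytest.raises(ValueError):
        kobe_classify(-0.1, 1.0)


def test_closed_loop_recovery_contains_truth():
    """Viable cloud contains the generating pair; median MSY_q within 30%."""
    r_true, kq_true = 1.0, 1000.0
    msy_true = r_true * kq_true / 4
    idx = schaefer_index(r_true, kq_true, 500.0, [0.8 * msy_true] * 8)
    priors = AMSYPriors(index=idx, bk_prior=(0.4, 0.6))
    result, ensemble = assess(idx, priors, n_samples=3000, seed=4)
    viable = ensemble.to_frame().query("viable")
    near_truth = (
        (np.abs(np.log(viable["r"] / r_true)) < 0.15)
        & (np.abs(np.log(viable["kq"] / kq_true)) < 0.15)
    )
    assert near_truth.any()
    assert abs(result.msy_q - msy_true) / msy_true < 0.3
    assert sum(result.status_probs.values()) == pytest.approx(1.0)


def test_assessment_deterministic():
    idx = schaefer_index(1.0, 1000.0, 500.0, [200.0] * 8)
    res1, _ = assess(idx, n_samples=2000, seed=9)
    res2, _ = assess(idx, n_samples=2000, seed=9)
    pd.testing.assert_frame_equal(res1.table, res2.table)
    assert res1.status_probs == res2.status_probs


def test_wider_r_prior_does_not_lose_viable_pairs():
    idx = schaefer_index(1.0, 1000.0, 500.0, [200.0] * 8)
    counts = []
    for r_hi in (1.2, 1.5, 2.0):
        priors = AMSYPriors(index=idx, r_range=(0.6, r_hi))
        ens = sample_rkq(priors, n_samples=4000, seed=13)
        out = filter_viable(ens, idx, priors, seed=17)
        counts.append(out.n_viable)
    assert counts[0] <= counts[1] <= counts[2]


def test_healthy_and_depleted_scenarios_classify_as_expected():
    r, kq = 1.0, 1000.0
    healthy = schaefer_index(r, kq, 650.0, [0.3 * r * kq / 4] * 8)
    res_h, _ = assess(
        healthy, AMSYPriors(index=healthy, bk_prior=(0.55, 0.75)),
        n_samples=4000, seed=21,
    )
    assert res_h.table["kobe"].iloc[-1] == "green"
    assert res_h.status_probs["green"] > 0.5
    # constant overfishing (F = 0.6 > F_MSY = r/2) pins B/K near 0.4
    a = [450.0]
    for _ in range(8):
        a.append(a[-1] + a[-1] * r * (1 - a[-1] / kq) - 0.6 * a[-1])
    depleted = pd.DataFrame({"year": np.arange(2014, 2023), "index": a})
    res_d, _ = assess(
        depleted, AMSYPriors(index=depleted, bk_prior=(0.2, 0.4)),
        n_samples=4000, seed=22,
    )
    assert res_d.table["b_bmsy_med"].iloc[-1] < 1.0


def test_mean_seasonal_index():
    def season(vals):
        return pd.DataFrame({"year": [2014, 2015], "index": vals})

    out = mean_seasonal_index(season([10, 40]), season([20, 50]), season([30, 60]))
    np.testing.assert_allclose(out["index"], [20.0, 50.0])
    same = season([7, 7])
    out2 = mean_seasonal_index(same, same.copy(), same.copy())
    np.testing.assert_allclose(out2["index"], [7.0, 7.0])
    with pytest.raises(ValueError, match="2015"):
        mean_seasonal_index(
            season([1, 2]), season([1, 2]),
            pd.DataFrame({"year": [2014], "index": [1.0]}),
        )
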