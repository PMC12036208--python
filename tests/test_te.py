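"""Time-to-event models: parametric CDFs, Turnbull NPMLE, kernel smoothing."""

import math

import numpy as np
import pytest

import respcurve as rc


def test_te_cdf_medians_and_limits():
    p = dict(b=4.0, d=1.0, e=48.0)
    assert rc.te_cdf("TE_LL4", p, 48.0) == pytest.approx(0.5)
    assert rc.te_cdf("TE_LN", p, 48.0) == pytest.approx(0.5)
    assert rc.te_cdf("TE_LL4", p, 0.0) == 0.0
    assert rc.te_cdf("TE_W", dict(b=2.0, d=0.6, e=30.0), math.inf) \
        == pytest.approx(0.6)


@pytest.mark.parametrize("mid", rc.TE_MODELS)
def test_te_cdf_monotone_and_bounded(mid):
    p = dict(b=3.0, d=0.8, e=40.0)
    t = np.linspace(0, 500, 2000)
    F = rc.te_cdf(mid, p, t)
    assert np.all(np.diff(F) >= -1e-12)
    assert F.min() >= 0 and F.max() <= 0.8 + 1e-12


def test_te_cdf_invalid_params():
    with pytest.raises(ValueError):
        rc.te_cdf("TE_LL4", dict(b=4.0, d=1.5, e=48.0), 10.0)
    with pytest.raises(KeyError):
        rc.te_cdf("TE_X", dict(b=1, d=1, e=1), 10.0)


def test_parametric_recovery_large_n(te_large):
    ds, recipe = te_large
    fit = rc.fit_te_parametric(ds, "TE_LL4")
    for name in ("b", "d", "e"):
        assert fit.params[name] == pytest.approx(recipe.params[name], rel=0.05)
    assert fit.params["d"] <= 1.0
    assert fit.covariance is not None
    assert np.all(np.diag(fit.covariance) > 0)


def test_parametric_zero_events_errors():
    recs = [rc.TERecord(("a",), 1, 0.0, 2.0, 0),
            rc.TERecord(("a",), 1, 2.0, 4.0, 0)]
    ds = rc.TimeToEventDataset(recs, {(("a",), 1): 50}).with_censored_remainder()
    with pytest.raises(rc.TEFitError):
        rc.fit_te_parametric(ds, "TE_LL4")


def test_parametric_single_interval_not_identifiable():
    recs = [rc.TERecord(("a",), 1, 0.0, 2.0, 100)]
    ds = rc.TimeToEventDataset(recs, {(("a",), 1): 100})
    with pytest.raises(rc.TEFitError):
        rc.fit_te_parametric(ds, "TE_LL4")


def test_turnbull_nonoverlapping_masses_are_proportions(te_toy):
    fit = rc.turnbull_npmle(te_toy)
    finite = dict(zip(fit.intervals, fit.masses))
    assert finite[(0.0, 2.0)] == pytest.approx(0.2, abs=1e-12)
    assert finite[(2.0, 4.0)] == pytest.approx(0.3, abs=1e-12)
    assert finite[(4.0, 6.0)] == pytest.approx(0.1, abs=1e-12)
    assert fit.masses.sum() == pytest.approx(1.0)
    assert fit.cdf_max() == pytest.approx(0.6)
    assert fit.residual < 1e-8


def test_turnbull_single_interval_mass_one():
    recs = [rc.TERecord(("a",), 1, 0.0, 2.0, 100)]
    ds = rc.TimeToEventDataset(recs, {(("a",), 1): 100})
    fit = rc.turnbull_npmle(ds)
    assert fit.masses.sum() == pytest.approx(1.0)
    assert fit.intervals == [(0.0, 2.0)]


def test_turnbull_overlapping_intervals_self_consistent():
    # replicates inspected on different schedules -> overlapping intervals
    recs = [rc.TERecord(("a",), 1, 0.0, 3.0, 30),
            rc.TERecord(("a",), 1, 3.0, 6.0, 20),
            rc.TERecord(("a",), 2, 0.0, 2.0, 10),
            rc.TERecord(("a",), 2, 2.0, 5.0, 25),
            rc.TERecord(("a",), 2, 5.0, 8.0, 15)]
    ds = rc.TimeToEventDataset(recs, {(("a",), 1): 50, (("a",), 2): 50})
    fit = rc.turnbull_npmle(ds)
    assert fit.residual < 1e-8
    assert np.all(fit.masses >= 0)
    assert fit.masses.sum() == pytest.approx(1.0)


def test_npmle_loglik_dominates_parametric(te_large):
    ds, _ = te_large
    np_fit = rc.turnbull_npmle(ds)
    for mid in rc.TE_MODELS:
        par = rc.fit_te_parametric(ds, mid)
        assert np_fit.loglik >= par.loglik - 1e-6


def test_kde_limit_reproduces_npmle_step(te_toy):
    np_fit = rc.turnbull_npmle(te_toy)
    kde = rc.kde_smooth(np_fit, bandwidth=1e-4)
    for t in (2.0, 4.0, 6.0):
        assert kde.cdf(t + 1e-3) == pytest.approx(np_fit.cdf(t), abs=1e-3)


def test_kde_monotone_and_auto_bandwidth(te_toy):
    np_fit = rc.turnbull_npmle(te_toy)
    kde = rc.kde_smooth(np_fit, "auto")
    assert 0 < kde.bandwidth < math.inf
    grid = np.linspace(0.0, 10.0, 1000)
    F = kde.cdf(grid)
    assert np.all(np.diff(F) >= -1e-12)
    assert F.max() <= 1.0 + 1e-9
    with pytest.raises(ValueError):
        rc.kde_smooth(np_fit, -1.0)


def test_te_information_criteria_use_interval_loglik(te_large):
    ds, _ = te_large
    fit = rc.fit_te_parametric(ds, "TE_W")
    assert fit.aic == pytest.approx(-2 * fit.loglik + 6.0)
    assert fit.bic == pytest.approx(-2 * fit.loglik + 3 * math.log(fit.n_obs))
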