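"""Least-squares fitting, information criteria, and model selection."""

import math

import numpy as np
import pytest

import respcurve as rc


def test_noiseless_ll4_exact_recovery(ll4_noiseless):
    ds, recipe = ll4_noiseless
    fit = rc.fit_dose_response(ds, "LL.4", seed=1)
    np.testing.assert_allclose(fit.theta, recipe.theta, rtol=1e-6)
    assert fit.converged
    assert fit.rss == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("mid,theta", [
    ("LL.5", (2.0, 5.0, 95.0, 3.0, 2.0)),
    ("W1.4", (2.0, 5.0, 95.0, 3.0)),
    ("W2.4", (-2.0, 5.0, 95.0, 3.0)),
    ("BC.5", (2.0, 0.0, 100.0, 10.0, 5.0)),
    ("CRS.5a", (2.0, 0.0, 100.0, 10.0, 60.0)),
])
def test_noiseless_recovery_other_families(mid, theta):
    doses = rc.default_doses(9, 0.003, 300.0)
    recipe = rc.DRRecipe(mid, theta, doses=doses, noise_sd=0.0, seed=2)
    ds = rc.simulate_dose_response(recipe)
    fit = rc.fit_dose_response(ds, mid, seed=2)
    np.testing.assert_allclose(fit.theta, theta, rtol=1e-4, atol=1e-4)


def test_self_start_is_finite_and_reasonable(ll4_noiseless):
    ds, recipe = ll4_noiseless
    start = rc.self_start(ds, rc.get_model("LL.4"))
    assert np.all(np.isfinite(start))
    e0 = start[3]
    assert recipe.theta[3] / 3 <= e0 <= recipe.theta[3] * 3


def test_self_start_degenerate_inputs():
    recs = [rc.DRRecord((), 1, d, 50.0) for d in (0.0, 1.0, 10.0)]
    ds = rc.DoseResponseDataset(recs)
    start = rc.self_start(ds, rc.get_model("LL.4"))
    assert np.all(np.isfinite(start))


def test_covariance_properties(ll4_noisy):
    ds, _ = ll4_noisy
    fit = rc.fit_dose_response(ds, "LL.4", seed=7)
    cov = fit.covariance
    np.testing.assert_allclose(cov, cov.T, rtol=1e-10)
    assert np.all(np.diag(cov) > 0)
    assert fit.df_resid == fit.n_obs - 4


def test_information_criteria_identity(ll4_noisy):
    ds, _ = ll4_noisy
    fit = rc.fit_dose_response(ds, "LL.4", seed=7)
    aic, bic = rc.information_criteria(fit)
    p = fit.n_params + 1  # variance counted
    assert bic - aic == pytest.approx(p * (math.log(fit.n_obs) - 2))
    # independent recomputation of the Gaussian AIC from RSS
    n = fit.n_obs
    sigma2 = fit.rss / n
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1)
    assert aic == pytest.approx(-2 * loglik + 2 * p, rel=1e-12)


def test_select_best_model_single_candidate(ll4_noisy):
    ds, _ = ll4_noisy
    fit = rc.select_best_model(ds, ["W1.4"], "AIC", seed=7)
    assert fit.spec.id == "W1.4"


def test_select_best_model_prefers_hormesis_on_hormetic_data(bc5_dataset):
    ds, _ = bc5_dataset
    fit = rc.select_best_model(ds, ["LL.4", "BC.5"], "AIC", seed=11)
    assert fit.spec.id == "BC.5"


def test_selected_model_beats_constant_mean(ll4_noisy):
    ds, _ = ll4_noisy
    fit = rc.select_best_model(ds, rc.list_candidate_models("monotonic"),
                               "AIC", seed=7)
    rss_const = float(((ds.responses - ds.responses.mean()) ** 2).sum())
    assert fit.rss <= rss_const


def test_fitting_is_deterministic(ll4_noisy):
    ds, _ = ll4_noisy
    f1 = rc.fit_dose_response(ds, "LL.4", seed=3)
    f2 = rc.fit_dose_response(ds, "LL.4", seed=3)
    np.testing.assert_array_equal(f1.theta, f2.theta)


def test_constant_response_flagged():
    recs = [rc.DRRecord((), r, d, 50.0)
            for d in (0.0, 0.1, 1.0, 10.0, 100.0) for r in (1, 2)]
    ds = rc.DoseResponseDataset(recs)
    try:
        fit = rc.fit_dose_response(ds, "LL.4", seed=0)
    except rc.FitError:
        return  # non-identifiable is an acceptable outcome
    assert abs(fit.theta[0]) < 1e-3 or fit.messages  # b ~ 0 or flagged


def test_too_few_observations_rejected():
    recs = [rc.DRRecord((), 1, d, v) for d, v in
            [(0.0, 100.0), (1.0, 50.0), (10.0, 10.0)]]
    ds = rc.DoseResponseDataset(recs)
    with pytest.raises(rc.FitError):
        rc.fit_dose_response(ds, "LL.5", seed=0)


def test_j_shaped_curve_fit_by_reflection():
    # dip-then-rise data: simulate an inverted-J and flip it
    recipe = rc.DRRecipe("BC.5", (2.0, 0.0, 100.0, 10.0, 5.0),
                         doses=rc.default_doses(8, 0.01, 300.0),
                         noise_sd=2.0, seed=13)
    ds = rc.simulate_dose_response(recipe)
    flipped = rc.DoseResponseDataset(
        [rc.DRRecord(r.factors, r.replicate, r.dose, 120.0 - r.response)
         for r in ds.records], shape="biphasic")
    fit = rc.fit_dose_response(flipped, "BC.5", seed=13)
    assert fit.reflection_applied
    # predictions live on the original (flipped) scale
    y0 = fit.predict(0.0)
    yM = fit.predict(10.0)
    assert y0 == pytest.approx(120.0 - 100.0, abs=5.0)
    resid = flipped.responses - np.asarray(fit.predict(flipped.doses))
    assert float(resid @ resid) / len(resid) < 25.0
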