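"""ED50/T50 estimation methods, hormesis metrics, range restriction."""

import math

import numpy as np
import pytest

import respcurve as rc
from respcurve.effective_dose import _ed_value


def _exact_fit(mid, theta, cov_scale=1.0):
    """A FittedCurve holding exact parameters and an arbitrary covariance."""
    spec = rc.get_model(mid)
    p = spec.n_params
    cov = cov_scale * np.diag(np.linspace(0.5, 1.5, p))
    return rc.FittedCurve(spec=spec, theta=np.asarray(theta, float),
                          covariance=cov, rss=1.0, loglik=0.0, n_obs=40,
                          dose_range=(0.0, 1000.0))


def test_ll4_relative_ed50_is_e_with_matching_se():
    fit = _exact_fit("LL.4", (1.0, 0.0, 100.0, 10.0))
    est = rc.ed50_delta(fit, "relative", 0.5)
    assert est.value == 10.0
    assert est.se == pytest.approx(math.sqrt(fit.covariance[3, 3]), rel=1e-12)
    assert est.ci[0] < est.value < est.ci[1]


def test_ll5_relative_ed50_matches_closed_form_and_root():
    b, c, d, e, f = 1.0, 0.0, 100.0, 10.0, 2.0
    fit = _exact_fit("LL.5", (b, c, d, e, f))
    est = rc.ed50_delta(fit, "relative", 0.5)
    closed = e * (2.0 ** (1.0 / f) - 1.0) ** (1.0 / b)
    assert est.value == pytest.approx(closed, rel=1e-9)
    # independent brute-force root of fitted(x) = 50
    grid = np.geomspace(1e-4, 1e4, 2_000_001)
    y = np.asarray(fit.predict(grid))
    i = int(np.argmin(np.abs(y - 50.0)))
    assert est.value == pytest.approx(grid[i], rel=1e-5)


def test_delta_method_low_phase_refused_for_biphasic():
    fit = _exact_fit("BC.5", (2.0, 0.0, 100.0, 10.0, 5.0))
    with pytest.raises(rc.CapabilityError, match="serra_greco"):
        rc.ed50_delta(fit, "relative", phase="low")


def test_interpolation_exact_ll4_absolute():
    fit = _exact_fit("LL.4", (1.0, 0.0, 100.0, 10.0))
    ests = rc.ed50_interpolation(fit, "absolute", 50.0)
    assert len(ests) == 1
    assert ests[0].value == pytest.approx(10.0, rel=1e-3)


def test_interpolation_biphasic_matches_brute_force():
    theta = (2.0, 0.0, 100.0, 10.0, 5.0)
    fit = _exact_fit("BC.5", theta)
    ests = {e.phase: e for e in rc.ed50_interpolation(fit, "absolute", 50.0)}
    grid = np.geomspace(1e-4, 1e3, 1_000_001)
    y = np.asarray(fit.predict(grid))
    m = rc.biphasic_metrics(fit)
    lo_seg = grid <= m.M
    hi_seg = grid > m.M
    # low phase has no 50 crossing here (curve starts at 100 and rises);
    # high phase must match the scan
    hi_cross = grid[hi_seg][np.argmin(np.abs(y[hi_seg] - 50.0))]
    assert ests["high"].value == pytest.approx(hi_cross, rel=1e-3)
    assert not ests["low"].in_range


def test_biphasic_metrics_match_brute_force_scan():
    theta = (2.0, 0.0, 100.0, 10.0, 5.0)
    fit = _exact_fit("BC.5", theta)
    m = rc.biphasic_metrics(fit)
    grid = np.geomspace(1e-4, 1e3, 1_000_001)
    y = np.asarray(fit.predict(grid))
    M_scan = grid[int(np.argmax(y))]
    assert m.M == pytest.approx(M_scan, rel=1e-3)
    y0 = fit.predict(0.0)
    after = grid > m.M
    LDS_scan = grid[after][int(np.argmin(np.abs(y[after] - y0)))]
    assert m.LDS == pytest.approx(LDS_scan, rel=1e-3)
    assert fit.predict(m.LDS) == pytest.approx(y0, abs=1e-6)
    assert m.M < m.LDS


def test_biphasic_metrics_undefined_at_f_zero():
    fit = _exact_fit("BC.5", (2.0, 0.0, 100.0, 10.0, 0.0))
    m = rc.biphasic_metrics(fit)
    assert not m.defined
    assert math.isnan(m.M)


def test_phase_ordering_low_M_high_LDS():
    theta = (3.0, 0.0, 100.0, 10.0, 30.0)
    fit = _exact_fit("BC.5", theta)
    m = rc.biphasic_metrics(fit)
    ests = {e.phase: e for e in rc.ed50_interpolation(fit, "relative", 0.5)}
    assert ests["low"].value < m.M < ests["high"].value < m.LDS


def test_reed_muench_hand_interpolation():
    import pandas as pd
    agg = pd.DataFrame({"dose": [1.0, 10.0], "mean": [60.0, 40.0]})
    est = rc.ed50_reed_muench(agg, 50.0, n_boot=0)
    assert est.value == pytest.approx(10.0 ** 0.5, rel=1e-12)


def test_reed_muench_exact_hit_and_errors():
    import pandas as pd
    agg = pd.DataFrame({"dose": [1.0, 10.0, 100.0], "mean": [80.0, 50.0, 20.0]})
    assert rc.ed50_reed_muench(agg, 50.0, n_boot=0).value == 10.0
    high = pd.DataFrame({"dose": [1.0, 10.0], "mean": [90.0, 70.0]})
    with pytest.raises(rc.NoSolutionError):
        rc.ed50_reed_muench(high, 50.0, n_boot=0)


def test_reed_muench_bootstrap_ci():
    recipe = rc.DRRecipe("LL.4", (1.5, 0.0, 100.0, 3.0), noise_sd=5.0, seed=21)
    ds = rc.simulate_dose_response(recipe)
    agg = rc.aggregate_by_dose(ds)
    est = rc.ed50_reed_muench(agg, 50.0, raw=ds, n_boot=300, seed=21)
    assert est.se is not None and est.se > 0
    assert est.ci[0] < est.value < est.ci[1]


def test_t50_parametric_examples():
    fit = rc.TEFit("TE_LL4", dict(b=4.0, d=1.0, e=48.0), None, 0.0, 100, 168.0)
    assert rc.t50_estimate(fit, "absolute").value == pytest.approx(48.0, rel=1e-6)
    assert rc.t50_estimate(fit, "relative").value == pytest.approx(48.0, rel=1e-6)
    low = rc.TEFit("TE_LL4", dict(b=4.0, d=0.4, e=48.0), None, 0.0, 100, 168.0)
    abs_est = rc.t50_estimate(low, "absolute")
    assert not abs_est.in_range
    assert rc.t50_estimate(low, "relative").value == pytest.approx(48.0, rel=1e-6)


def test_t50_npmle_midpoint_linear(te_toy):
    fit = rc.turnbull_npmle(te_toy)
    est = rc.t50_estimate(fit, "absolute")
    assert est.value == pytest.approx(4.0, abs=1e-6)


def test_restrict_to_range():
    est = rc.EffectiveDoseEstimate("ED50", "relative", "single",
                                   "ritz_gerhard", 10.0)
    ok = rc.restrict_to_range(est, (0.0, 100.0))
    assert ok.in_range and ok.masked_value() == 10.0
    out = rc.restrict_to_range(
        rc.EffectiveDoseEstimate("ED50", "relative", "single",
                                 "ritz_gerhard", 150.0), (0.0, 100.0))
    assert not out.in_range and math.isnan(out.masked_value())
    edge = rc.restrict_to_range(
        rc.EffectiveDoseEstimate("ED50", "relative", "single",
                                 "ritz_gerhard", 100.0), (0.0, 100.0))
    assert edge.in_range  # closed upper bound


def test_ci_brackets_estimate_whenever_produced(ll4_noisy):
    ds, _ = ll4_noisy
    fit = rc.fit_dose_response(ds, "LL.4", seed=7)
    for est in [rc.ed50_delta(fit, "relative"),
                *rc.ed50_interpolation(fit, "relative")]:
        if est.ci is not None:
            assert est.ci[0] < est.value < est.ci[1]
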