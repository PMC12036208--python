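"""Model-assessment tests: structure, preconditions, and concordance."""

import numpy as np
import pytest

import respcurve as rc
from respcurve.assessment import AssessmentError


@pytest.fixture
def fit_and_data(ll4_noisy):
    ds, _ = ll4_noisy
    return rc.fit_dose_response(ds, "LL.4", seed=7), ds


def test_lack_of_fit_structure(fit_and_data):
    fit, ds = fit_and_data
    res = rc.lack_of_fit_test(fit, ds)
    n = len(ds.records)
    k = len(ds.distinct_doses())
    assert res.df == (k - fit.n_params, n - k)
    assert 0 <= res.p <= 1
    assert res.statistic >= 0


def test_lack_of_fit_requires_replicates():
    recs = [rc.DRRecord((), 1, d, v) for d, v in
            zip(rc.default_doses(8), 100 / (1 + (rc.default_doses(8) / 3)))]
    ds = rc.DoseResponseDataset(recs)
    fit = rc.fit_dose_response(ds, "LL.4", seed=0)
    with pytest.raises(AssessmentError, match="Neill"):
        rc.lack_of_fit_test(fit, ds)


def test_neill_matches_classic_with_dose_grouping(fit_and_data):
    fit, ds = fit_and_data
    lof = rc.lack_of_fit_test(fit, ds)
    nei = rc.neill_test(fit, ds, grouping="doses")
    assert nei.statistic == pytest.approx(lof.statistic, rel=1e-10)
    assert nei.p == pytest.approx(lof.p, rel=1e-10)


def test_neill_without_replicates_pair_grouping():
    doses = rc.default_doses(10, 0.01, 100.0, include_zero=False)
    rng = np.random.default_rng(5)
    y = 100 / (1 + (doses / 3) ** 2) + rng.normal(0, 3, doses.size)
    recs = [rc.DRRecord((), 1, float(d), float(v)) for d, v in zip(doses, y)]
    ds = rc.DoseResponseDataset(recs)
    fit = rc.fit_dose_response(ds, "LL.4", seed=5)
    res = rc.neill_test(fit, ds)  # adjacent-pair default
    assert np.isfinite(res.statistic)
    assert 0 <= res.p <= 1


def test_neill_too_few_groups_errors():
    doses = np.array([0.1, 1.0, 10.0])
    recs = [rc.DRRecord((), r, float(d), float(100 / (1 + d)))
            for d in doses for r in (1, 2)]
    ds = rc.DoseResponseDataset(recs)
    fit = rc.fit_dose_response(ds, "LL.4", seed=0)
    with pytest.raises(AssessmentError, match="groups"):
        rc.neill_test(fit, ds, grouping=[doses[:2], doses[2:]])


def test_no_effect_detects_strong_signal(fit_and_data):
    fit, ds = fit_and_data
    res = rc.no_effect_test(fit, ds)
    assert res.p < 1e-6
    assert res.statistic >= 0


def test_no_effect_near_one_on_flat_data():
    rng = np.random.default_rng(9)
    recs = [rc.DRRecord((), r, float(d), float(rng.normal(50, 5)))
            for d in rc.default_doses(7) for r in (1, 2, 3)]
    ds = rc.DoseResponseDataset(recs)
    try:
        fit = rc.fit_dose_response(ds, "LL.4", seed=9)
    except rc.FitError:
        pytest.skip("flat data may be non-identifiable")
    res = rc.no_effect_test(fit, ds)
    assert res.p > 0.05


def test_parameter_wald_tests(fit_and_data):
    fit, ds = fit_and_data
    tests = rc.parameter_wald_tests(fit)
    assert [t.name for t in tests] == ["param_b", "param_c", "param_d",
                                       "param_e"]
    for t in tests:
        assert 0 <= t.p <= 1
    # d (upper plateau ~95) is overwhelmingly nonzero
    d_test = dict((t.name, t) for t in tests)["param_d"]
    assert d_test.p < 1e-10


def test_assess_report_bundles_everything(fit_and_data):
    fit, ds = fit_and_data
    report = rc.assess(fit, ds)
    names = [r["test"] for r in report.to_rows()]
    assert "lack_of_fit" in names
    assert "neill" in names
    assert "no_effect" in names
    assert sum(n.startswith("param_") for n in names) == fit.n_params
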