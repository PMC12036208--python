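"""Functional forms, limits, reduction identities, and analytic gradients."""

import numpy as np
import pytest

import respcurve as rc

THETAS = {
    "LL.4": (1.7, 3.0, 95.0, 4.0),
    "LL.5": (1.7, 3.0, 95.0, 4.0, 2.2),
    "W1.4": (1.7, 3.0, 95.0, 4.0),
    "W2.4": (1.7, 3.0, 95.0, 4.0),
    "BC.5": (1.7, 3.0, 95.0, 4.0, 8.0),
    "CRS.5a": (1.7, 3.0, 95.0, 4.0, 40.0),
    "CRS.5b": (1.7, 3.0, 95.0, 4.0, 40.0),
    "CRS.5c": (1.7, 3.0, 95.0, 4.0, 40.0),
    "CRS.4a": (1.7, 95.0, 4.0, 40.0),
    "CRS.4b": (1.7, 95.0, 4.0, 40.0),
    "CRS.4c": (1.7, 95.0, 4.0, 40.0),
}


def test_ll4_midpoint_and_zero_dose():
    spec = rc.get_model("LL.4")
    assert rc.evaluate_model(spec, (1, 0, 100, 10), 10.0) == pytest.approx(50.0)
    assert rc.evaluate_model(spec, (1, 0, 100, 10), 0.0) == pytest.approx(100.0)


@pytest.mark.parametrize("mid", ["BC.5", "CRS.5a", "CRS.5b", "CRS.5c"])
def test_hormesis_families_reduce_to_ll4_at_f_zero(mid):
    spec = rc.get_model(mid)
    ll4 = rc.get_model("LL.4")
    x = np.concatenate([[0.0], np.geomspace(1e-3, 1e3, 200)])
    y_h = rc.evaluate_model(spec, (1.7, 3.0, 95.0, 4.0, 0.0), x)
    y_l = rc.evaluate_model(ll4, (1.7, 3.0, 95.0, 4.0), x)
    np.testing.assert_allclose(y_h, y_l, rtol=1e-12)


def test_ll5_reduces_to_ll4_at_f_one():
    x = np.geomspace(1e-3, 1e3, 100)
    y5 = rc.evaluate_model(rc.get_model("LL.5"), (1.7, 3, 95, 4, 1.0), x)
    y4 = rc.evaluate_model(rc.get_model("LL.4"), (1.7, 3, 95, 4), x)
    np.testing.assert_allclose(y5, y4, rtol=1e-12)


@pytest.mark.parametrize("mid", ["LL.4", "LL.5", "W1.4"])
def test_asymptotes_for_positive_slope(mid):
    # d at dose -> 0+, c at dose -> infinity for b > 0
    spec = rc.get_model(mid)
    th = THETAS[mid]
    assert rc.evaluate_model(spec, th, 0.0) == pytest.approx(95.0, abs=1e-9)
    assert rc.evaluate_model(spec, th, 1e12) == pytest.approx(3.0, abs=1e-6)


def test_w2_limit_is_lower_asymptote_at_zero():
    # the Weibull-II form tends to c (not d) as dose -> 0 for b > 0
    spec = rc.get_model("W2.4")
    assert rc.evaluate_model(spec, THETAS["W2.4"], 0.0) == pytest.approx(3.0)
    assert rc.evaluate_model(spec, THETAS["W2.4"], 1e12) == pytest.approx(95.0)


@pytest.mark.parametrize("mid", ["LL.4", "LL.5", "W1.4", "W2.4"])
def test_monotonic_families_are_monotone(mid):
    spec = rc.get_model(mid)
    x = np.geomspace(1e-4, 1e4, 2000)
    y = rc.evaluate_model(spec, THETAS[mid], x)
    dy = np.diff(y)
    assert np.all(dy <= 1e-12) or np.all(dy >= -1e-12)


@pytest.mark.parametrize("mid", sorted(THETAS))
@pytest.mark.parametrize("x", [0.0, 0.05, 1.0, 4.0, 250.0])
def test_gradient_matches_finite_differences(mid, x):
    spec = rc.get_model(mid)
    th = np.array(THETAS[mid], dtype=float)
    g = rc.model_gradient(spec, th, x)
    fd = np.zeros_like(th)
    for i in range(th.size):
        h = 1e-6 * max(abs(th[i]), 1.0)
        tp, tm = th.copy(), th.copy()
        tp[i] += h
        tm[i] -= h
        fd[i] = (rc.evaluate_model(spec, tp, x)
                 - rc.evaluate_model(spec, tm, x)) / (2 * h)
    np.testing.assert_allclose(g, fd, rtol=1e-6, atol=1e-6)


def test_ll4_gradient_midpoint_symmetry():
    g = rc.model_gradient(rc.get_model("LL.4"), (1.0, 0.0, 100.0, 10.0), 10.0)
    # at x = e: dc = dd = 1/2, db = 0
    assert g[1] == pytest.approx(0.5)
    assert g[2] == pytest.approx(0.5)
    assert g[0] == pytest.approx(0.0, abs=1e-14)


def test_candidate_model_lists():
    mono = rc.list_candidate_models("monotonic")
    assert [s.id for s in mono] == ["LL.4", "LL.5", "W1.4", "W2.4"]
    bi = rc.list_candidate_models("biphasic")
    assert "BC.5" in [s.id for s in bi]
    assert all(s.id.startswith(("BC", "CRS")) for s in bi)
    assert len(rc.list_candidate_models("all")) == len(mono) + len(bi)
    with pytest.raises(ValueError):
        rc.list_candidate_models("sideways")


def test_invalid_parameters_rejected():
    spec = rc.get_model("LL.4")
    with pytest.raises(ValueError):
        rc.evaluate_model(spec, (1.0, 0.0, 100.0, -2.0), 1.0)  # e <= 0
    with pytest.raises(ValueError):
        rc.evaluate_model(spec, (1.0, 0.0, 100.0, 10.0), -1.0)  # dose < 0
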