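"""Model-assessment tests for dose-response fits.

Four complementary checks of a fitted curve:

* lack-of-fit: F test of the parametric curve against the saturated
  one-mean-per-dose ANOVA (needs replicates);
* Neill's test: the same idea made workable without true replicates by
  grouping neighbouring doses (with replicates and per-dose grouping it
  reduces to the classic lack-of-fit test);
* no-effect: F test of the curve against the constant-mean model -- is
  there any dose-response relationship at all;
* parameters-different-from-zero: per-parameter Wald t tests (the hormesis
  parameter f being the one of most interest for biphasic fits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import DoseResponseDataset
from .fitting import FittedCurve

__all__ = [
    "TestResult",
    "AssessmentReport",
    "AssessmentError",
    "lack_of_fit_test",
    "neill_test",
    "no_effect_test",
    "parameter_wald_tests",
    "assess",
]


class AssessmentError(ValueError):
    """The requested test is not computable on this design."""


@dataclass
class TestResult:
    name: str
    statistic: float
    df: tuple[int, ...]
    p: float
    detail: str = ""


@dataclass
class AssessmentReport:
    lack_of_fit: TestResult | None
    neill: TestResult | None
    no_effect: TestResult
    parameter_tests: list[TestResult] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        rows = []
        for t in [self.lack_of_fit, self.neill, self.no_effect,
                  *self.parameter_tests]:
            if t is None:
                continue
            rows.append({"test": t.name, "statistic": t.statistic,
                         "df": "/".join(str(d) for d in t.df), "p": t.p,
                         "detail": t.detail})
        return rows


def _model_rss(fit: FittedCurve, ds: DoseResponseDataset) -> tuple[float, np.ndarray, np.ndarray]:
    x = ds.doses
    y = ds.responses
    resid = y - np.asarray(fit.predict(x))
    return float(resid @ resid), x, y


def lack_of_fit_test(fit: FittedCurve, ds: DoseResponseDataset) -> TestResult:
    """Classic replicate-based lack-of-fit F test.

    Compares the model RSS against the pure-error RSS of the saturated
    one-mean-per-dose model; a small p flags systematic misfit.
    """
    rss_m, x, y = _model_rss(fit, ds)
    uniq = np.unique(x)
    if all((x == u).sum() < 2 for u in uniq):
        raise AssessmentError(
            "lack-of-fit needs replicated doses; use Neill's test instead")
    rss_pe = float(sum(((y[x == u] - y[x == u].mean()) ** 2).sum()
                       for u in uniq))
    df_m = x.size - fit.n_params
    df_pe = x.size - uniq.size
    if df_m <= df_pe:
        raise AssessmentError(
            "model is saturated (parameters >= distinct doses): lack-of-fit "
            "undefined")
    num = (rss_m - rss_pe) / (df_m - df_pe)
    den = rss_pe / df_pe
    F = num / den if den > 0 else math.inf
    p = float(stats.f.sf(F, df_m - df_pe, df_pe)) if math.isfinite(F) else 0.0
    return TestResult("lack_of_fit", float(F), (df_m - df_pe, df_pe), p)


def _default_grouping(uniq: np.ndarray) -> list[np.ndarray]:
    """Consecutive non-overlapping dose pairs; an odd leftover dose joins
    the last group."""
    groups = [uniq[i:i + 2] for i in range(0, uniq.size - 1, 2)]
    if uniq.size % 2 == 1:
        if groups:
            groups[-1] = np.concatenate([groups[-1], uniq[-1:]])
        else:
            groups = [uniq]
    return groups


def neill_test(fit: FittedCurve, ds: DoseResponseDataset,
               grouping: str | list | None = None) -> TestResult:
    """Neill's grouping-based lack-of-fit test.

    ``grouping`` may be ``"doses"`` (each distinct dose its own group;
    requires replicates and reproduces the classic test) or a list of dose
    arrays; the default groups adjacent dose pairs so the test works
    without replicates.
    """
    rss_m, x, y = _model_rss(fit, ds)
    uniq = np.unique(x)
    if grouping is None:
        # with replicated doses each dose is its own group (the classic
        # lack-of-fit grouping); without replicates fall back to pairs
        if any((x == u).sum() >= 2 for u in uniq):
            grouping = "doses"
        else:
            groups = _default_grouping(uniq)
    if grouping == "doses":
        groups = [np.array([u]) for u in uniq]
    elif grouping is not None:
        groups = [np.asarray(g, dtype=float) for g in grouping]
    T = len(groups)
    n = x.size
    if T <= fit.n_params:
        raise AssessmentError(
            f"Neill's test needs more groups than parameters "
            f"({T} groups <= {fit.n_params} parameters)")
    member = np.full(n, -1)
    for gi, g in enumerate(groups):
        member[np.isin(x, g)] = gi
    if np.any(member < 0):
        raise AssessmentError("grouping does not cover every tested dose")
    rss_g = 0.0
    for gi in range(T):
        sel = member == gi
        if sel.sum() < 2:
            raise AssessmentError(
                "every group must contain at least 2 observations")
        rss_g += float(((y[sel] - y[sel].mean()) ** 2).sum())
    df1 = T - fit.n_params
    df2 = n - T
    if df2 <= 0:
        raise AssessmentError("no residual degrees of freedom within groups")
    F = ((rss_m - rss_g) / df1) / (rss_g / df2) if rss_g > 0 else math.inf
    F = max(F, 0.0) if math.isfinite(F) else F
    p = float(stats.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
    return TestResult("neill", float(F), (df1, df2), p,
                      detail=f"{T} dose groups")


def no_effect_test(fit: FittedCurve, ds: DoseResponseDataset) -> TestResult:
    """Likelihood-ratio test of the fitted curve against the constant-mean
    (no dose effect) model.

    The statistic is n log(RSS_null / RSS_model), referred to chi-square
    with (p - 1) degrees of freedom; a model no better than the null gives
    a statistic near 0 and p near 1 (not an error).
    """
    rss_m, x, y = _model_rss(fit, ds)
    rss_0 = float(((y - y.mean()) ** 2).sum())
    df1 = fit.n_params - 1
    if rss_0 < rss_m - 1e-9 * max(rss_0, 1.0):
        raise AssertionError(
            "null RSS below model RSS: least-squares nesting violated "
            "(fitter bug)")
    if rss_m <= 0:
        return TestResult("no_effect", math.inf, (df1,), 0.0)
    lrt = max(x.size * math.log(rss_0 / rss_m), 0.0)
    p = float(stats.chi2.sf(lrt, df1))
    return TestResult("no_effect", float(lrt), (df1,), p)


def parameter_wald_tests(fit: FittedCurve) -> list[TestResult]:
    """Per-parameter Wald t tests against zero ("parameters != 0")."""
    out = []
    for i, name in enumerate(fit.spec.parameter_names):
        est = float(fit.theta[i])
        se = float(np.sqrt(fit.covariance[i, i]))
        if se == 0:
            raise AssessmentError(
                f"parameter {name!r} has zero standard error: degenerate "
                "covariance")
        t = est / se
        p = float(2 * stats.t.sf(abs(t), fit.df_resid))
        out.append(TestResult(f"param_{name}", t, (fit.df_resid,), p,
                              detail=f"estimate={est:.6g}, se={se:.3g}"))
    return out


def assess(fit: FittedCurve, ds: DoseResponseDataset) -> AssessmentReport:
    """All four tests in one report; tests whose preconditions fail are
    reported as absent rather than aborting the run."""
    try:
        lof = lack_of_fit_test(fit, ds)
    except AssessmentError:
        lof = None
    try:
        nei = neill_test(fit, ds)
    except AssessmentError:
        nei = None
    return AssessmentReport(lof, nei, no_effect_test(fit, ds),
                            parameter_wald_tests(fit))
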