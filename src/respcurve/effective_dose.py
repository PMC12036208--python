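"""ED50 / T50 estimation, hormesis metrics, and range restriction.

Three estimation methods are provided, each with a distinct capability
profile:

* ``ritz_gerhard`` -- invert the fitted curve analytically or by root
  finding and propagate parameter uncertainty by the delta method.  For
  biphasic curves only the high-phase (second-phase) ED50 is available.
* ``serra_greco`` -- interpolation on a dense log-spaced dose grid of the
  fitted curve, with confidence limits read off where the pointwise
  delta-method confidence band crosses the target level.  Handles both
  phases of J- and inverted-J-shaped curves.
* ``reed_muench`` -- classic linear interpolation between the two observed
  dose means that bracket the target level (log10-dose scale by default);
  needs no model fit, so it also serves incomplete curves.  Uncertainty by
  replicate bootstrap.

Absolute estimates target a fixed response level on a control-normalized
scale (50 on the percent scale by default); relative estimates target the
midpoint of the span between the fitted asymptotes (per phase for biphasic
curves, spanning from the phase's asymptote to the response at the
extremum dose M).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .fitting import FittedCurve

__all__ = [
    "EffectiveDoseEstimate",
    "BiphasicMetrics",
    "CapabilityError",
    "NoSolutionError",
    "ed50_delta",
    "ed50_interpolation",
    "ed50_reed_muench",
    "biphasic_metrics",
    "t50_estimate",
    "restrict_to_range",
]


class CapabilityError(ValueError):
    """The requested method cannot produce this estimate type."""


class NoSolutionError(RuntimeError):
    """The fitted curve never reaches the target level."""


@dataclass
class EffectiveDoseEstimate:
    kind: str  # "ED50" | "T50"
    basis: str  # "absolute" | "relative"
    phase: str  # "single" | "low" | "high"
    method: str  # "ritz_gerhard" | "serra_greco" | "reed_muench"
    value: float
    se: float | None = None
    ci: tuple[float, float] | None = None
    in_range: bool = True
    level: float = 0.5
    note: str = ""

    def masked_value(self):
        """Value for user-facing tables: hidden when outside the tested range."""
        return self.value if self.in_range else math.nan


@dataclass
class BiphasicMetrics:
    M: float  # dose of maximal stimulation (inverted-J) / inhibition (J)
    LDS: float  # limiting dose: second-phase dose matching the control response
    f_estimate: float
    f_se: float
    f_p: float
    max_effect_response: float
    defined: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# helpers

def _z_crit(ci_level: float) -> float:
    return float(stats.norm.ppf(0.5 + ci_level / 2.0))


def _phase_asymptote(fit: FittedCurve, phase: str) -> float:
    """Reference asymptote of a phase on the original response scale.

    The low phase starts from the dose-zero plateau, the high phase decays
    toward the parameter-c plateau (reflected back if a J-shaped curve was
    fit on the flipped scale).
    """
    if phase == "low":
        return float(fit.predict(0.0))
    c = fit.param("c") if "c" in fit.spec.parameter_names \
        else float(fit.spec.fixed_constants.get("c", 0.0))
    return fit.reflection_offset - c if fit.reflection_applied else c


def _target_level(fit: FittedCurve, basis: str, level: float,
                  phase: str = "single") -> float:
    if basis == "absolute":
        return level
    if fit.spec.shape_class == "monotonic":
        y0 = float(fit.predict(0.0))
        # high-dose plateau by numeric limit: families differ in which
        # parameter plays that role (W2 runs opposite to LL/W1)
        y_inf = float(fit.predict(fit.param("e") * 1e12))
        lo, hi = min(y_inf, y0), max(y_inf, y0)
        return lo + level * (hi - lo)
    # biphasic: span from the phase asymptote to the response at M
    M = _argext_dose(fit)
    yM = float(fit.predict(M))
    a = _phase_asymptote(fit, phase)
    return a + level * (yM - a)


def _search_bounds(fit: FittedCurve) -> tuple[float, float]:
    e = fit.param("e")
    lo = min(fit.dose_range[0] if fit.dose_range[0] > 0 else e, e) * 1e-6
    hi = max(fit.dose_range[1] if math.isfinite(fit.dose_range[1]) else e, e) * 1e6
    return max(lo, 1e-300), hi


def _bracketed_root(func, lo, hi, n_scan=400):
    """Scan a log grid for a sign change, then polish with brentq."""
    grid = np.geomspace(lo, hi, n_scan)
    vals = np.array([func(g) for g in grid])
    sign = np.sign(vals)
    idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    exact = np.flatnonzero(vals == 0)
    if exact.size:
        return float(grid[exact[0]])
    if idx.size == 0:
        raise NoSolutionError("target level not crossed inside search range")
    i = idx[0]
    return float(optimize.brentq(func, grid[i], grid[i + 1], xtol=1e-14,
                                 rtol=8.9e-16, maxiter=200))


def _argext_dose(fit: FittedCurve, n_grid: int = 4001) -> float:
    """Dose of the curve's extremum (max for inverted-J on the original
    scale; the reflection bookkeeping makes this a maximum of the raw fit
    either way)."""
    lo, hi = _search_bounds(fit)
    grid = np.geomspace(lo, hi, n_grid)
    sgn = -1.0 if fit.reflection_applied else 1.0
    y = sgn * np.asarray(fit.predict(grid))
    i = int(np.argmax(y))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    if a == b:
        return float(grid[i])
    res = optimize.minimize_scalar(lambda x: -sgn * float(fit.predict(x)),
                                   bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-12})
    return float(res.x)


def _ed_value(fit: FittedCurve, basis: str, level: float, phase: str) -> float:
    """Dose solving fitted(x) = target for the requested phase."""
    spec = fit.spec
    if (spec.id == "LL.4" and basis == "relative" and not fit.reflection_applied):
        # closed form: the relative ED at level q of LL.4 is e (q=1/2) or
        # e * ((1-q)/q)^(-1/b) ... solve L = level directly
        e = fit.param("e")
        if level == 0.5:
            return e
        b = fit.param("b")
        return e * ((1.0 - level) / level) ** (-1.0 / b)
    target = _target_level(fit, basis, level, phase)
    lo, hi = _search_bounds(fit)
    if spec.shape_class == "biphasic":
        M = _argext_dose(fit)
        lo, hi = (lo, M) if phase == "low" else (M, hi)
    return _bracketed_root(lambda x: float(fit.predict(x)) - target, lo, hi)


def _ed_gradient(fit: FittedCurve, basis: str, level: float, phase: str,
                 rel_step: float = 1e-6) -> np.ndarray:
    """d ED / d theta by central differences of the full ED map.

    Differentiating the map itself (rather than using the implicit-function
    formula) keeps closed-form cases exact: for an LL.4 relative ED50 the
    map is theta -> e, so the gradient is exactly (0, 0, 0, 1)."""
    theta0 = fit.theta.copy()
    g = np.zeros_like(theta0)
    for i in range(theta0.size):
        h = rel_step * max(abs(theta0[i]), 1e-3)
        tp, tm = theta0.copy(), theta0.copy()
        tp[i] = theta0[i] + h
        tm[i] = theta0[i] - h
        fp = replace(fit, theta=tp)
        fm = replace(fit, theta=tm)
        try:
            ep = _ed_value(fp, basis, level, phase)
            em = _ed_value(fm, basis, level, phase)
        except (NoSolutionError, ValueError):
            g[i] = np.nan
            continue
        g[i] = (ep - em) / (tp[i] - tm[i])
    return g


# ---------------------------------------------------------------------------
# method 1: delta method (Ritz-Gerhard)

def ed50_delta(fit: FittedCurve, basis: str = "relative", level: float = 0.5,
               phase: str | None = None,
               ci_level: float = 0.95) -> EffectiveDoseEstimate:
    """ED50 by curve inversion with a delta-method standard error.

    For biphasic fits only ``phase='high'`` is supported; request the
    interpolation method (``serra_greco``) for the low phase.
    """
    biphasic = fit.spec.shape_class == "biphasic"
    if phase is None:
        phase = "high" if biphasic else "single"
    if biphasic and phase != "high":
        raise CapabilityError(
            "the delta method (ritz_gerhard) reports only the high ED50 of a "
            "biphasic curve; use the serra_greco interpolation method for the "
            "low phase")
    if not biphasic:
        phase = "single"
    value = _ed_value(fit, basis, level, phase)
    g = _ed_gradient(fit, basis, level, phase)
    if np.all(np.isfinite(g)):
        var = float(g @ fit.covariance @ g)
        se = math.sqrt(max(var, 0.0))
        z = _z_crit(ci_level)
        ci = (value - z * se, value + z * se)
    else:
        se, ci = None, None
    return EffectiveDoseEstimate("ED50", basis, phase, "ritz_gerhard",
                                 value, se, ci, level=level)


# ---------------------------------------------------------------------------
# method 2: grid interpolation (Serra-Greco)

def _grid_for(fit: FittedCurve, n_grid: int) -> np.ndarray:
    lo, hi = fit.dose_range
    if hi <= 0:
        raise NoSolutionError("no positive doses tested")
    if lo <= 0:
        # dose 0 was tested: extend the log grid below the smallest nonzero
        # dose so crossings inside (0, min positive dose] remain locatable
        return np.geomspace(_min_positive(fit) / 1000.0, hi, n_grid)
    return np.geomspace(lo, hi, n_grid)


def _min_positive(fit: FittedCurve) -> float:
    lo, hi = fit.dose_range
    if lo > 0:
        return lo
    # smallest positive dose is not stored on the fit; fall back to a fixed
    # fraction of the span anchored at the location parameter
    e = fit.param("e")
    return min(e, hi) / 100.0


def _crossings(grid: np.ndarray, y: np.ndarray, target: float) -> list[float]:
    """All inverse-interpolated crossings of y(grid) through target."""
    out = []
    diff = y - target
    exact = np.flatnonzero(diff == 0)
    for i in exact:
        out.append(float(grid[i]))
    s = np.sign(diff)
    idx = np.flatnonzero(s[:-1] * s[1:] < 0)
    lg = np.log(grid)
    for i in idx:
        w = diff[i] / (diff[i] - diff[i + 1])
        out.append(float(np.exp(lg[i] + w * (lg[i + 1] - lg[i]))))
    return sorted(out)


def ed50_interpolation(fit: FittedCurve, basis: str = "relative",
                       level: float = 0.5, n_grid: int = 10_000,
                       ci_level: float = 0.95) -> list[EffectiveDoseEstimate]:
    """ED50 by dense-grid interpolation of the fitted curve (Serra-Greco).

    Returns one estimate for monotonic fits and up to two (low/high phase)
    for biphasic fits.  Confidence limits are the doses at which the
    pointwise delta-method confidence band crosses the target level within
    the same phase; crossings outside the tested dose range are reported
    with ``in_range=False``.
    """
    grid = _grid_for(fit, n_grid)
    y = np.asarray(fit.predict(grid))
    se_y = fit.predict_se(grid)
    z = _z_crit(ci_level)
    biphasic = fit.spec.shape_class == "biphasic"

    estimates: list[EffectiveDoseEstimate] = []
    if not biphasic:
        target = _target_level(fit, basis, level, "single")
        xs = _crossings(grid, y, target)
        if not xs:
            return [EffectiveDoseEstimate(
                "ED50", basis, "single", "serra_greco", math.nan,
                in_range=False, level=level,
                note="target level not reached inside the tested dose range")]
        value = xs[0]
        ci = _band_ci(grid, y, se_y, z, target, value)
        estimates.append(EffectiveDoseEstimate(
            "ED50", basis, "single", "serra_greco", value, None, ci,
            level=level))
        return estimates

    M = _argext_dose(fit)
    for phase in ("low", "high"):
        target = _target_level(fit, basis, level, phase)
        seg = grid <= M if phase == "low" else grid >= M
        xs = _crossings(grid[seg], y[seg], target)
        if not xs:
            estimates.append(EffectiveDoseEstimate(
                "ED50", basis, phase, "serra_greco", math.nan,
                in_range=False, level=level,
                note=f"{phase}-phase target not crossed inside tested range"))
            continue
        value = xs[0] if phase == "low" else xs[-1] if basis == "relative" else xs[0]
        ci = _band_ci(grid[seg], y[seg], se_y[seg], z, target, value)
        estimates.append(EffectiveDoseEstimate(
            "ED50", basis, phase, "serra_greco", value, None, ci, level=level))
    return estimates


def _band_ci(grid, y, se_y, z, target, value):
    lo_band = _crossings(grid, y - z * se_y, target)
    hi_band = _crossings(grid, y + z * se_y, target)
    cand = []
    for xs in (lo_band, hi_band):
        if xs:
            cand.append(min(xs, key=lambda x: abs(math.log(x) - math.log(value))))
    if len(cand) != 2:
        return None
    return (min(cand), max(cand))


# ---------------------------------------------------------------------------
# method 3: Reed and Muench

def ed50_reed_muench(agg, level: float = 50.0, scale: str = "log10",
                     ci_level: float = 0.95, n_boot: int = 2000,
                     seed: int = 0,
                     raw: "object | None" = None) -> EffectiveDoseEstimate:
    """Absolute ED50 by linear interpolation between the two bracketing
    dose means (Reed and Muench).

    ``agg`` is the per-dose table from :func:`respcurve.aggregate_by_dose`
    (columns dose/mean, one curve only).  Interpolation runs on log10 dose
    by default; a pair that includes dose 0 falls back to the linear dose
    scale.  When ``raw`` (the originating DoseResponseDataset) is supplied,
    SE and a percentile CI are produced by bootstrap over replicates.
    """
    doses = np.asarray(agg["dose"], dtype=float)
    means = np.asarray(agg["mean"], dtype=float)
    order = np.argsort(doses)
    doses, means = doses[order], means[order]
    value, note = _reed_muench_value(doses, means, level, scale)

    se = ci = None
    if raw is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        by_dose = {float(d): [r.response for r in raw.records if r.dose == d]
                   for d in doses}
        boots = []
        for _ in range(n_boot):
            bm = np.array([np.mean(rng.choice(by_dose[float(d)],
                                              size=len(by_dose[float(d)]),
                                              replace=True))
                           for d in doses])
            try:
                v, _ = _reed_muench_value(doses, bm, level, scale)
                boots.append(v)
            except NoSolutionError:
                continue
        if len(boots) >= max(20, n_boot // 10):
            boots = np.array(boots)
            se = float(boots.std(ddof=1))
            a = (1 - ci_level) / 2
            ci = (float(np.quantile(boots, a)), float(np.quantile(boots, 1 - a)))

    return EffectiveDoseEstimate("ED50", "absolute", "single", "reed_muench",
                                 value, se, ci, level=level, note=note)


def _reed_muench_value(doses, means, level, scale):
    exact = np.flatnonzero(means == level)
    if exact.size:
        return float(doses[exact[0]]), ""
    diff = means - level
    sgn = np.sign(diff)
    idx = np.flatnonzero(sgn[:-1] * sgn[1:] < 0)
    if idx.size == 0:
        raise NoSolutionError(
            "no adjacent dose pair brackets the target level")
    note = "" if idx.size == 1 else \
        "multiple bracketing pairs (non-monotone means); first crossing used"
    i = idx[0]
    x1, x2, y1, y2 = doses[i], doses[i + 1], means[i], means[i + 1]
    if scale == "log10" and x1 > 0:
        l1, l2 = math.log10(x1), math.log10(x2)
        led = l1 + (level - y1) * (l2 - l1) / (y2 - y1)
        return 10.0 ** led, note
    value = x1 + (level - y1) * (x2 - x1) / (y2 - y1)
    return float(value), note or ("linear-scale interpolation (pair includes dose 0)"
                                  if x1 == 0 else "")


# ---------------------------------------------------------------------------
# biphasic metrics

def biphasic_metrics(fit: FittedCurve, ci_level: float = 0.95) -> BiphasicMetrics:
    """M, LDS and the hormesis parameter f for a biphasic fit.

    M is the dose of the extremum response; LDS is the second-phase dose at
    which the curve returns to the untreated-control (dose-zero) response.
    The hormesis magnitude f is reported with its Wald test against zero.
    """
    if fit.spec.shape_class != "biphasic":
        raise CapabilityError("biphasic metrics require a biphasic model fit")
    f_hat = fit.param("f")
    f_se = fit.se("f")
    if f_se > 0:
        t = f_hat / f_se
        f_p = float(2 * stats.t.sf(abs(t), fit.df_resid))
    else:
        f_p = math.nan

    y0 = float(fit.predict(0.0))
    M = _argext_dose(fit)
    yM = float(fit.predict(M))
    sgn = -1.0 if fit.reflection_applied else 1.0
    if f_hat == 0 or sgn * (yM - y0) <= 0:
        return BiphasicMetrics(math.nan, math.nan, f_hat, f_se, f_p, yM,
                               defined=False,
                               note="no detectable hormetic phase (f ~ 0)")
    lo, hi = _search_bounds(fit)
    try:
        LDS = _bracketed_root(lambda x: float(fit.predict(x)) - y0, M, hi)
    except NoSolutionError:
        LDS = math.nan
    return BiphasicMetrics(M, LDS, f_hat, f_se, f_p, yM)


# ---------------------------------------------------------------------------
# T50

def t50_estimate(fit, basis: str = "absolute", level: float = 0.5,
                 ci_level: float = 0.95,
                 time_range: tuple[float, float] | None = None) -> EffectiveDoseEstimate:
    """T50 from a parametric, NPMLE or kernel-smoothed time-to-event fit.

    Absolute: smallest t with F(t) >= level (whole sample).  Relative:
    smallest t with F(t)/F_max >= level, where F_max is the fitted upper
    asymptote d (parametric) or the CDF at the last observation time
    (nonparametric).  Estimates are flagged out of range when the level is
    never reached inside the observed time frame.
    """
    from .te import KDEFit, NPMLEFit, TEFit  # local import to avoid cycle

    if isinstance(fit, TEFit):
        est = _t50_parametric(fit, basis, level, ci_level)
    elif isinstance(fit, NPMLEFit):
        est = _t50_quantile(fit.cdf, fit.cdf_max(), fit.t_max(), basis, level)
        est.method = "npmle"
    elif isinstance(fit, KDEFit):
        est = _t50_quantile(fit.cdf, fit.cdf_max(), fit.t_max, basis, level)
        est.method = "kde"
    else:
        raise TypeError(f"unsupported fit object {type(fit).__name__}")
    if time_range is not None:
        est = restrict_to_range(est, time_range)
    return est


def _t50_parametric(fit, basis, level, ci_level):
    d = fit.params["d"]
    target = level if basis == "absolute" else level * d
    if target >= d:
        return EffectiveDoseEstimate(
            "T50", basis, "single", "ritz_gerhard", math.nan,
            in_range=False, level=level,
            note=f"maximum fitted response {d:.3f} is below the requested level")
    t_hi = fit.t_max * 1e6 if fit.t_max > 0 else 1e9
    value = _bracketed_root(lambda t: fit.cdf(t) - target,
                            max(fit.t_max * 1e-9, 1e-12), t_hi)
    if fit.covariance is None:
        return EffectiveDoseEstimate("T50", basis, "single", "ritz_gerhard",
                                     value, level=level)
    g = np.zeros(3)
    names = ("b", "d", "e")
    for i, name in enumerate(names):
        h = 1e-6 * max(abs(fit.params[name]), 1e-3)
        pp = dict(fit.params)
        pm = dict(fit.params)
        pp[name] += h
        pm[name] -= h
        if name == "d":  # keep the asymptote inside its (0, 1] domain
            pp[name] = min(pp[name], 1.0)
            pm[name] = max(pm[name], 1e-9)
        tgt_p = level if basis == "absolute" else level * pp["d"]
        tgt_m = level if basis == "absolute" else level * pm["d"]
        try:
            vp = _bracketed_root(
                lambda t: fit.cdf(t, params=pp) - tgt_p,
                max(fit.t_max * 1e-9, 1e-12), t_hi)
            vm = _bracketed_root(
                lambda t: fit.cdf(t, params=pm) - tgt_m,
                max(fit.t_max * 1e-9, 1e-12), t_hi)
            g[i] = (vp - vm) / (pp[name] - pm[name])
        except NoSolutionError:
            g[i] = np.nan
    se = ci = None
    if fit.covariance is not None and np.all(np.isfinite(g)):
        var = float(g @ fit.covariance @ g)
        if var >= 0:
            se = math.sqrt(var)
            z = _z_crit(ci_level)
            ci = (value - z * se, value + z * se)
    return EffectiveDoseEstimate("T50", basis, "single", "ritz_gerhard",
                                 value, se, ci, level=level)


def _t50_quantile(cdf, cdf_max, t_max, basis, level):
    target = level if basis == "absolute" else level * cdf_max
    if cdf_max < target or cdf_max <= 0:
        return EffectiveDoseEstimate(
            "T50", basis, "single", "npmle", math.nan, in_range=False,
            level=level,
            note=f"CDF reaches only {cdf_max:.3f} within the observed frame")
    # smallest t with F(t) >= target on a fine grid, bisection-refined
    lo, hi = 0.0, t_max
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cdf(mid) >= target:
            hi = mid
        else:
            lo = mid
    return EffectiveDoseEstimate("T50", basis, "single", "npmle",
                                 float(hi), level=level)


# ---------------------------------------------------------------------------
# range restriction

def restrict_to_range(est: EffectiveDoseEstimate,
                      observed_range: tuple[float, float]) -> EffectiveDoseEstimate:
    """Flag estimates outside the tested dose/time range.

    Extrapolating a fitted curve beyond the tested range is unreliable, so
    out-of-range estimates keep their raw value internally but are masked in
    user-facing tables (closed upper bound: a value equal to the range
    maximum is in range).
    """
    lo, hi = observed_range
    if not math.isfinite(est.value):
        return replace(est, in_range=False)
    ok = lo < est.value <= hi if lo == 0 else lo <= est.value <= hi
    if not ok:
        return replace(est, in_range=False,
                       note=(est.note + "; " if est.note else "")
                       + f"estimate {est.value:.4g} outside tested range "
                         f"({lo:g}, {hi:g}]")
    return replace(est, in_range=True)
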