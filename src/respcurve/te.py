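"""Interval-censored time-to-event models: parametric ML, Turnbull NPMLE,
and kernel-smoothed CDFs.

The observed data are counts of events inside inspection intervals
``(time_before, time_after]`` (e.g. seeds found germinated between two
visits), with right censoring encoded as ``time_after = inf``.  All fits in
this module pool replicates within a factor combination.

Parametric families (t = time, all with 0 < d <= 1 the fraction of
ultimately-responding individuals and e > 0 a time-location parameter;
b > 0 so every CDF is non-decreasing):

* ``TE_LL4`` (log-logistic): F(t) = d / (1 + exp(-b (ln t - ln e)))
* ``TE_W``   (Weibull)     : F(t) = d (1 - exp(-(t/e)**b))
* ``TE_LN``  (log-normal)  : F(t) = d * Phi(b (ln t - ln e))

F(e) = d/2 for the log-logistic and log-normal families.  The likelihood is
the interval-censored one: an individual observed to respond in (l, r]
contributes F(r) - F(l); a right-censored individual contributes 1 - F(l)
(never-responders, fraction 1 - d, are part of that term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import TimeToEventDataset

__all__ = [
    "TE_MODELS",
    "TEFit",
    "NPMLEFit",
    "KDEFit",
    "TEFitError",
    "te_cdf",
    "fit_te_parametric",
    "turnbull_npmle",
    "kde_smooth",
]

TE_MODELS = ("TE_LL4", "TE_W", "TE_LN")


class TEFitError(RuntimeError):
    """Time-to-event fit failed (no information, non-identifiable, ...)."""


def te_cdf(model_id: str, params: dict, t) -> np.ndarray | float:
    """CDF of a parametric event-time family at time(s) ``t``."""
    b, d, e = params["b"], params["d"], params["e"]
    if not (0 < d <= 1):
        raise ValueError(f"upper asymptote d must lie in (0, 1], got {d}")
    if e <= 0 or b <= 0:
        raise ValueError("parameters b and e must be > 0")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    out = np.zeros_like(t)
    pos = t > 0
    inf = np.isinf(t)
    fin = pos & ~inf
    lt = np.log(t[fin]) - math.log(e)
    if model_id == "TE_LL4":
        out[fin] = d / (1.0 + np.exp(np.clip(-b * lt, -700, 700)))
    elif model_id == "TE_W":
        out[fin] = d * (1.0 - np.exp(-np.minimum((t[fin] / e) ** b, 700.0)))
    elif model_id == "TE_LN":
        out[fin] = d * stats.norm.cdf(b * lt)
    else:
        raise KeyError(f"unknown TE model {model_id!r}; known: {TE_MODELS}")
    out[inf] = d
    return float(out[0]) if scalar else out


@dataclass
class TEFit:
    """A maximum-likelihood parametric time-to-event fit."""

    model_id: str
    params: dict  # {"b", "d", "e"}
    covariance: np.ndarray | None
    loglik: float
    n_obs: int  # total individuals
    t_max: float
    aic: float = math.nan
    bic: float = math.nan
    converged: bool = True
    curve_id: tuple[str, ...] = ()
    kind: str = "TE"

    @property
    def n_params(self) -> int:
        return 3

    def cdf(self, t, params: dict | None = None):
        return te_cdf(self.model_id, params or self.params, t)

    def se(self, name: str) -> float:
        i = ("b", "d", "e").index(name)
        if self.covariance is None:
            return math.nan
        return float(np.sqrt(self.covariance[i, i]))

    def summary(self) -> dict:
        return {"model": self.model_id, "parameters": [
            {"parameter": k, "estimate": self.params[k], "se": self.se(k)}
            for k in ("b", "d", "e")],
            "loglik": self.loglik, "aic": self.aic, "bic": self.bic,
            "n_obs": self.n_obs, "converged": self.converged}


def _pooled(ds: TimeToEventDataset):
    """Replicate-pooled (l, r, n) triples with n > 0."""
    triples = [(lo, hi, n) for lo, hi, n in ds.pooled_intervals() if n > 0]
    if not triples:
        raise TEFitError("dataset holds no counts")
    return triples


def _neg_loglik(model_id, triples):
    L = np.array([t[0] for t in triples])
    R = np.array([t[1] for t in triples])
    n = np.array([t[2] for t in triples], dtype=float)

    def nll(psi):
        b, d, e = np.exp(psi[0]), 1.0 / (1.0 + np.exp(-psi[1])), np.exp(psi[2])
        p = dict(b=b, d=d, e=e)
        FL = te_cdf(model_id, p, L)
        FR = np.where(np.isinf(R), 1.0, te_cdf(model_id, p,
                                               np.where(np.isinf(R), 1.0, R)))
        prob = np.clip(FR - FL, 1e-300, None)
        return -float(np.sum(n * np.log(prob)))

    return nll, (L, R, n)


def fit_te_parametric(ds: TimeToEventDataset, model_id: str) -> TEFit:
    """Interval-censored maximum likelihood for one parametric family.

    Replicates are pooled within the curve; the covariance is the inverse
    observed information at the optimum (finite-difference Hessian on the
    natural b, d, e scale).
    """
    from scipy import optimize

    if model_id not in TE_MODELS:
        raise KeyError(f"unknown TE model {model_id!r}; known: {TE_MODELS}")
    if len(ds.curve_ids()) > 1:
        raise TEFitError("fit_te_parametric expects a single curve; subset first")
    triples = _pooled(ds)
    finite = [t for t in triples if math.isfinite(t[1])]
    events = sum(t[2] for t in finite)
    total = sum(t[2] for t in triples)
    if events == 0:
        raise TEFitError("no events observed: the likelihood is uninformative")
    if len(finite) < 2:
        raise TEFitError(
            "all events fall in a single interval: parameters are not "
            "identifiable")
    t_max = max(t[1] for t in finite)

    # moment-style start: response fraction, rough median, moderate slope
    d0 = min(max(events / total, 0.02), 0.98)
    cum = np.cumsum([t[2] for t in finite]) / events
    med_idx = int(np.searchsorted(cum, 0.5))
    e0 = max(finite[min(med_idx, len(finite) - 1)][1], 1e-6)
    nll, _ = _neg_loglik(model_id, triples)

    best = None
    for b0 in (1.0, 3.0, 8.0):
        psi0 = np.array([math.log(b0),
                         math.log(d0 / (1 - d0)), math.log(e0)])
        res = optimize.minimize(nll, psi0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 4000})
        res = optimize.minimize(nll, res.x, method="BFGS",
                                options={"gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    psi = best.x
    b, d, e = float(np.exp(psi[0])), float(1 / (1 + np.exp(-psi[1]))), \
        float(np.exp(psi[2]))
    params = dict(b=b, d=d, e=e)
    loglik = -float(best.fun)

    cov = _observed_information_cov(model_id, params, triples)
    fit = TEFit(model_id, params, cov, loglik, n_obs=total, t_max=t_max,
                converged=bool(best.success or
                               np.linalg.norm(best.jac
                                              if hasattr(best, "jac") and
                                              best.jac is not None else 0)
                               < 1e-3),
                curve_id=ds.curve_ids()[0])
    p = 3
    fit.aic = -2 * loglik + 2 * p
    fit.bic = -2 * loglik + p * math.log(total)
    return fit


def _observed_information_cov(model_id, params, triples, rel_h=1e-5):
    """Finite-difference Hessian of -logL on the natural parameter scale."""
    names = ("b", "d", "e")
    x0 = np.array([params[k] for k in names])

    def f(x):
        p = dict(zip(names, x))
        if not (p["b"] > 0 and 0 < p["d"] <= 1 and p["e"] > 0):
            return math.inf
        nll, _ = _neg_loglik(model_id, triples)
        psi = np.array([math.log(p["b"]),
                        math.log(p["d"] / (1 - p["d"])) if p["d"] < 1 else 30.0,
                        math.log(p["e"])])
        return nll(psi)

    h = rel_h * np.maximum(np.abs(x0), 1e-3)
    # keep d strictly inside (0, 1)
    h[1] = min(h[1], 0.49 * min(params["d"], 1 - params["d"]) + 1e-12)
    H = np.empty((3, 3))
    f0 = f(x0)
    for i in range(3):
        for j in range(i, 3):
            xi, xj = np.zeros(3), np.zeros(3)
            xi[i], xj[j] = h[i], h[j]
            if i == j:
                H[i, i] = (f(x0 + xi) - 2 * f0 + f(x0 - xi)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + xi + xj) - f(x0 + xi - xj)
                    - f(x0 - xi + xj) + f(x0 - xi - xj)) / (4 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        return None
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(cov) <= 0):
        return None
    return cov


# ---------------------------------------------------------------------------
# Turnbull NPMLE

@dataclass
class NPMLEFit:
    """Turnbull nonparametric MLE over equivalence-class intervals.

    ``intervals`` are the Turnbull (left, right] classes, possibly ending
    with an unbounded class carrying right-censored mass; ``masses`` aligns
    with them and sums to 1.  The CDF is uniquely defined only outside the
    classes; inside, the evaluator interpolates per ``convention``
    ("midpoint-linear", linear across the class, or "right-endpoint", a
    step at the class's right end).
    """

    intervals: list[tuple[float, float]]
    masses: np.ndarray
    loglik: float
    n_obs: int
    residual: float
    n_iter: int
    convention: str = "midpoint-linear"
    curve_id: tuple[str, ...] = ()

    @property
    def finite_mask(self) -> np.ndarray:
        return np.array([math.isfinite(r) for _, r in self.intervals])

    def finite_masses(self) -> np.ndarray:
        return self.masses[self.finite_mask]

    def cdf_max(self) -> float:
        return float(self.finite_masses().sum())

    def t_max(self) -> float:
        fins = [r for _, r in self.intervals if math.isfinite(r)]
        return max(fins) if fins else 0.0

    def cdf(self, t) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t_arr)
        cum = 0.0
        for (l, r), m in zip(self.intervals, self.masses):
            if not math.isfinite(r):
                continue
            before = t_arr <= l
            after = t_arr >= r
            inside = ~before & ~after
            out[after] += m
            if self.convention == "midpoint-linear":
                out[inside] += m * (t_arr[inside] - l) / (r - l)
            # right-endpoint convention adds nothing inside the class
            cum += m
        return float(out[0]) if np.asarray(t).ndim == 0 else out


def _turnbull_classes(triples):
    """Innermost (Turnbull) intervals of a set of (l, r] observations."""
    lefts = sorted({l for l, _, _ in triples})
    rights = sorted({r for _, r, _ in triples})
    classes = []
    for q in lefts:
        cand = [p for p in rights if p > q]
        if not cand:
            continue
        p = cand[0]
        if any(q < l2 < p for l2 in lefts):
            continue
        classes.append((q, p))
    return classes


def turnbull_npmle(ds: TimeToEventDataset, tol: float = 1e-10,
                   max_iter: int = 10_000,
                   convention: str = "midpoint-linear") -> NPMLEFit:
    """Nonparametric maximum-likelihood CDF by self-consistency EM.

    Probability mass is assigned to the Turnbull equivalence classes; the
    fixed point of the self-consistency equations is the NPMLE.  For
    non-overlapping observation intervals the masses are exactly the
    empirical proportions.
    """
    if convention not in ("midpoint-linear", "right-endpoint"):
        raise ValueError(f"unknown convention {convention!r}")
    triples = _pooled(ds)
    classes = _turnbull_classes(triples)
    if not classes:
        raise TEFitError("no Turnbull classes: dataset carries no information")
    J = len(classes)
    counts = np.array([n for _, _, n in triples], dtype=float)
    N = counts.sum()
    # membership: class j inside observation i
    A = np.zeros((len(triples), J))
    for i, (l, r, _) in enumerate(triples):
        for j, (q, p) in enumerate(classes):
            if q >= l and p <= r:
                A[i, j] = 1.0

    masses = np.full(J, 1.0 / J)
    it = 0
    for it in range(1, max_iter + 1):
        denom = A @ masses
        if np.any(denom <= 0):
            # an observation covers no positive-mass class; restart uniform
            masses = np.full(J, 1.0 / J)
            denom = A @ masses
        new = masses * (A.T @ (counts / denom)) / N
        new /= new.sum()
        if np.max(np.abs(new - masses)) < tol:
            masses = new
            break
        masses = new
    denom = A @ masses
    residual = float(np.max(np.abs(
        masses * (A.T @ (counts / denom)) / N - masses)))
    loglik = float(np.sum(counts * np.log(np.clip(denom, 1e-300, None))))
    return NPMLEFit(classes, masses, loglik, int(N), residual, it,
                    convention=convention,
                    curve_id=ds.curve_ids()[0] if ds.records else ())


# ---------------------------------------------------------------------------
# kernel smoothing

@dataclass
class KDEFit:
    """Gaussian-kernel smoothing of the NPMLE masses into a continuous CDF."""

    bandwidth: float
    centers: np.ndarray
    weights: np.ndarray
    t_max: float
    curve_id: tuple[str, ...] = ()

    def cdf(self, t) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        z = (t_arr[:, None] - self.centers[None, :]) / self.bandwidth
        out = (stats.norm.cdf(z) * self.weights[None, :]).sum(axis=1)
        return float(out[0]) if np.asarray(t).ndim == 0 else out

    def cdf_max(self) -> float:
        return float(self.weights.sum())


def kde_smooth(npmle: NPMLEFit, bandwidth: float | str = "auto") -> KDEFit:
    """Smooth the Turnbull step CDF with a Gaussian kernel.

    Mass of each finite Turnbull class sits at the class midpoint; the
    smoothed CDF is the weighted mixture of normal CDFs centred there.  As
    the bandwidth shrinks the smoothed CDF converges to the NPMLE step CDF
    at points outside the classes.  ``"auto"`` uses a weighted
    Silverman-style plug-in bandwidth.
    """
    mask = npmle.finite_mask
    centers = np.array([(l + r) / 2.0 for (l, r), keep
                        in zip(npmle.intervals, mask) if keep])
    weights = npmle.masses[mask]
    if centers.size == 0:
        raise TEFitError("no finite-interval mass to smooth")
    if bandwidth == "auto":
        w = weights / weights.sum()
        mu = float(np.sum(w * centers))
        sd = float(np.sqrt(np.sum(w * (centers - mu) ** 2)))
        n_eff = max(1.0 / float(np.sum(w**2)), 2.0)
        scale = sd if sd > 0 else max(npmle.t_max(), 1.0) / 10.0
        bandwidth = 0.9 * scale * n_eff ** (-0.2)
        bandwidth = max(bandwidth, 1e-6)
    if not (isinstance(bandwidth, (int, float)) and bandwidth > 0):
        raise ValueError("bandwidth must be a positive number or 'auto'")
    return KDEFit(float(bandwidth), centers, weights, npmle.t_max(),
                  curve_id=npmle.curve_id)
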