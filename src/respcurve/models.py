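"""Dose-response model families.

All curves are parameterized in the (b, c, d, e, f) convention standard in
dose-response analysis:

* ``b`` -- slope (steepness) parameter,
* ``c`` -- lower asymptote (response at infinite dose for b > 0),
* ``d`` -- upper asymptote (response at dose zero for b > 0),
* ``e`` -- location parameter on the dose axis (> 0); for the four-parameter
  log-logistic it is exactly the relative ED50,
* ``f`` -- asymmetry (five-parameter log-logistic) or hormesis magnitude
  (Brain-Cousens and Cedergreen-Ritz-Streibig families).

Functional forms (x = dose, all defined for x > 0 with the analytic limit
taken at x = 0):

* ``LL.4``   : c + (d - c) / (1 + exp(b (ln x - ln e)))
* ``LL.5``   : c + (d - c) / (1 + exp(b (ln x - ln e)))**f
* ``W1.4``   : c + (d - c) * exp(-exp(b (ln x - ln e)))
* ``W2.4``   : c + (d - c) * (1 - exp(-exp(b (ln x - ln e))))
* ``BC.5``   : c + (d - c + f x) / (1 + exp(b (ln x - ln e)))
* ``CRS.5*`` : c + (d - c + f exp(-1 / x**alpha)) / (1 + exp(b (ln x - ln e)))
  with alpha fixed at 1 (a), 0.5 (b) or 0.25 (c); ``CRS.4*`` variants fix
  c = 0.

The Brain-Cousens and CRS families reduce to LL.4 at f = 0, and LL.5 reduces
to LL.4 at f = 1; these identities are exercised by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelSpec",
    "get_model",
    "list_candidate_models",
    "evaluate_model",
    "model_gradient",
    "MODEL_REGISTRY",
]


@dataclass(frozen=True)
class ModelSpec:
    """Identity and parameter layout of a dose-response model family."""

    id: str
    n_params: int
    shape_class: str  # "monotonic" | "biphasic"
    parameter_names: tuple[str, ...]
    fixed_constants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.parameter_names) != self.n_params:
            raise ValueError("parameter_names length must equal n_params")

    @property
    def has_hormesis(self) -> bool:
        return self.shape_class == "biphasic"


def _spec(mid, names, shape, **consts) -> ModelSpec:
    return ModelSpec(id=mid, n_params=len(names), shape_class=shape,
                     parameter_names=tuple(names), fixed_constants=dict(consts))


MODEL_REGISTRY: dict[str, ModelSpec] = {
    s.id: s
    for s in [
        _spec("LL.4", "bcde", "monotonic"),
        _spec("LL.5", "bcdef", "monotonic"),
        _spec("W1.4", "bcde", "monotonic"),
        _spec("W2.4", "bcde", "monotonic"),
        _spec("BC.5", "bcdef", "biphasic"),
        _spec("CRS.5a", "bcdef", "biphasic", alpha=1.0),
        _spec("CRS.5b", "bcdef", "biphasic", alpha=0.5),
        _spec("CRS.5c", "bcdef", "biphasic", alpha=0.25),
        _spec("CRS.4a", "bdef", "biphasic", alpha=1.0, c=0.0),
        _spec("CRS.4b", "bdef", "biphasic", alpha=0.5, c=0.0),
        _spec("CRS.4c", "bdef", "biphasic", alpha=0.25, c=0.0),
    ]
}


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model id {model_id!r}; known: {sorted(MODEL_REGISTRY)}"
        ) from None


def list_candidate_models(shape: str = "all") -> list[ModelSpec]:
    """Candidate families for a declared curve shape.

    ``monotonic`` gives the four sigmoidal families, ``biphasic`` the
    hormesis families, ``all`` both.
    """
    if shape == "monotonic":
        ids = ["LL.4", "LL.5", "W1.4", "W2.4"]
    elif shape == "biphasic":
        ids = ["BC.5", "CRS.5a", "CRS.5b", "CRS.5c", "CRS.4a", "CRS.4b", "CRS.4c"]
    elif shape == "all":
        return list_candidate_models("monotonic") + list_candidate_models("biphasic")
    else:
        raise ValueError(f"unknown shape {shape!r}; expected monotonic|biphasic|all")
    return [MODEL_REGISTRY[i] for i in ids]


def _theta_dict(spec: ModelSpec, theta) -> dict[str, float]:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_params,):
        raise ValueError(
            f"{spec.id} expects {spec.n_params} parameters, got {theta.shape}"
        )
    p = dict(zip(spec.parameter_names, theta))
    p.setdefault("c", float(spec.fixed_constants.get("c", 0.0)))
    p.setdefault("f", 1.0 if spec.id == "LL.5" else 0.0)
    if p["e"] <= 0:
        raise ValueError(f"location parameter e must be > 0, got {p['e']}")
    if spec.id == "LL.5" and p["f"] <= 0:
        raise ValueError(f"LL.5 asymmetry f must be > 0, got {p['f']}")
    return p


def evaluate_model(spec: ModelSpec, theta, dose) -> np.ndarray | float:
    """Mean response of model ``spec`` with parameters ``theta`` at ``dose``.

    Dose 0 is handled by the analytic limit of the functional form.
    """
    p = _theta_dict(spec, theta)
    x = np.asarray(dose, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise ValueError("doses must be >= 0")
    y = _evaluate(spec, p, x)
    return float(y[0]) if scalar else y


def _logistic_term(p, x):
    """z = exp(b(ln x - ln e)) and L = 1/(1+z), with x=0 limits."""
    b, e = p["b"], p["e"]
    z = np.empty_like(x)
    pos = x > 0
    with np.errstate(over="ignore"):
        z[pos] = np.exp(np.clip(b * (np.log(x[pos]) - np.log(e)), -700, 700))
    # x -> 0+: z -> 0 for b > 0, +inf for b < 0, 1 for b = 0
    z[~pos] = 0.0 if b > 0 else (np.inf if b < 0 else 1.0)
    L = 1.0 / (1.0 + z)
    return z, L


def _numerator(spec, p, x):
    """Dose-dependent numerator N(x) of the logistic-quotient families."""
    c, d, f = p["c"], p["d"], p["f"]
    if spec.id == "BC.5":
        return d - c + f * x
    if spec.id.startswith("CRS"):
        alpha = spec.fixed_constants["alpha"]
        g = np.zeros_like(x)
        posx = x > 0
        g[posx] = np.exp(-1.0 / x[posx] ** alpha)  # -> 0 as x -> 0+
        return d - c + f * g
    return np.full_like(x, d - c)


def _evaluate(spec, p, x):
    c, d = p["c"], p["d"]
    z, L = _logistic_term(p, x)
    if spec.id == "LL.5":
        return c + (d - c) * L ** p["f"]
    if spec.id == "W1.4":
        return c + (d - c) * np.exp(-z)
    if spec.id == "W2.4":
        return c + (d - c) * (1.0 - np.exp(-np.minimum(z, 745.0)))
    return c + _numerator(spec, p, x) * L


def model_gradient(spec: ModelSpec, theta, dose) -> np.ndarray:
    """Gradient of the mean response with respect to the free parameters.

    Returns an array of shape ``(len(dose), n_params)`` (or ``(n_params,)``
    for scalar dose), columns ordered as ``spec.parameter_names``.
    """
    p = _theta_dict(spec, theta)
    x = np.asarray(dose, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise ValueError("doses must be >= 0")

    b, c, d, e, f = p["b"], p["c"], p["d"], p["e"], p["f"]
    z, L = _logistic_term(p, x)
    pos = x > 0
    u = np.zeros_like(x)
    u[pos] = np.log(x[pos]) - np.log(e)
    # d z / d b = u z ; d z / d e = -(b/e) z.  At x = 0 the products u*z and
    # z/(1+z)^2 vanish in the limit for either sign of b.
    finite = np.isfinite(z)
    with np.errstate(invalid="ignore", over="ignore"):
        return _gradient_branches(spec, p, x, z, L, u, pos, finite, scalar)


def _gradient_branches(spec, p, x, z, L, u, pos, finite, scalar):
    b, c, d, e, f = p["b"], p["c"], p["d"], p["e"], p["f"]
    L2z = np.where(finite, z * L * L, 0.0)  # z/(1+z)^2, -> 0 as z -> inf

    grads: dict[str, np.ndarray] = {}
    if spec.id in ("LL.4", "LL.5"):
        expo = f if spec.id == "LL.5" else 1.0
        Lf = L**expo
        # dLf/dz = -expo * L^(expo+1)
        dLf_dz = -expo * L ** (expo + 1.0)
        grads["b"] = (d - c) * np.where(finite & pos, dLf_dz * u * z, 0.0)
        grads["c"] = 1.0 - Lf
        grads["d"] = Lf
        grads["e"] = (d - c) * np.where(finite, dLf_dz * (-(b / e)) * z, 0.0)
        if spec.id == "LL.5":
            with np.errstate(divide="ignore"):
                logL = np.where(L > 0, np.log(L), 0.0)
            grads["f"] = (d - c) * Lf * logL
    elif spec.id in ("W1.4", "W2.4"):
        ez = np.exp(-np.minimum(z, 745.0))
        sgn = -1.0 if spec.id == "W1.4" else 1.0
        body = ez if spec.id == "W1.4" else 1.0 - ez
        grads["b"] = (d - c) * sgn * np.where(finite & pos, ez * u * z, 0.0)
        grads["c"] = 1.0 - body
        grads["d"] = body
        grads["e"] = (d - c) * sgn * np.where(finite, ez * (-(b / e)) * z, 0.0)
    else:  # BC.5 / CRS families: y = c + N(x) * L
        N = _numerator(spec, p, x)
        grads["b"] = -N * np.where(finite & pos, u * L2z, 0.0)
        grads["c"] = 1.0 - L
        grads["d"] = L
        grads["e"] = N * (b / e) * L2z
        if spec.id == "BC.5":
            grads["f"] = x * L
        else:
            alpha = spec.fixed_constants["alpha"]
            g = np.zeros_like(x)
            g[pos] = np.exp(-1.0 / x[pos] ** alpha)
            grads["f"] = g * L

    out = np.column_stack([grads[name] for name in spec.parameter_names])
    return out[0] if scalar else out
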