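"""Synthetic dose-response and time-to-event data with known truth.

The generators emulate the two experiment types the package analyzes:
plate-style dose-response assays (replicated responses with homoscedastic
Gaussian noise around a known curve) and germination-style time-to-event
assays (event times drawn from a known sub-distribution, a fraction of
never-responders, counts binned into inspection intervals).  Every draw is
fully determined by the recipe's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import DoseResponseDataset, DRRecord, TERecord, TimeToEventDataset
from .models import evaluate_model, get_model

__all__ = [
    "DRRecipe",
    "TERecipe",
    "simulate_dose_response",
    "simulate_time_to_event",
    "default_doses",
]


def default_doses(n: int = 7, lo: float = 0.01, hi: float = 100.0,
                  include_zero: bool = True) -> np.ndarray:
    """A log-spaced dose design with an untreated control."""
    doses = np.geomspace(lo, hi, n)
    return np.concatenate([[0.0], doses]) if include_zero else doses


@dataclass
class DRRecipe:
    """Truth + design for a simulated dose-response curve."""

    model_id: str
    theta: tuple
    doses: np.ndarray = field(default_factory=default_doses)
    replicates: int = 4
    noise_sd: float = 5.0
    proportional_noise: bool = False
    shape: str | None = None  # inferred from the model unless set
    factors: tuple[str, ...] = ("sim",)
    seed: int = 0


@dataclass
class TERecipe:
    """Truth + design for a simulated interval-censored germination assay."""

    model_id: str = "TE_LL4"
    params: dict = field(default_factory=lambda: dict(b=4.0, d=0.9, e=48.0))
    inspection_times: np.ndarray = field(
        default_factory=lambda: np.arange(12.0, 169.0, 12.0))
    n_individuals: int = 100
    replicates: int = 1
    factors: tuple[str, ...] = ("sim",)
    seed: int = 0


def simulate_dose_response(recipe: DRRecipe) -> DoseResponseDataset:
    """Responses on a known curve plus iid Gaussian noise.

    ``proportional_noise`` draws the sd as ``noise_sd`` percent of the
    local mean instead of a constant (robustness checks only).
    """
    spec = get_model(recipe.model_id)
    rng = np.random.default_rng(recipe.seed)
    doses = np.asarray(recipe.doses, dtype=float)
    if recipe.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    mu = np.asarray(evaluate_model(spec, recipe.theta, doses))
    records = []
    for rep in range(1, recipe.replicates + 1):
        sd = (np.abs(mu) * recipe.noise_sd / 100.0
              if recipe.proportional_noise else recipe.noise_sd)
        y = mu + sd * rng.standard_normal(doses.size)
        records.extend(
            DRRecord(recipe.factors, rep, float(d), float(v))
            for d, v in zip(doses, y))
    shape = recipe.shape or spec.shape_class
    return DoseResponseDataset(records, shape=shape,
                               factor_names=tuple(
                                   f"factor{i+1}"
                                   for i in range(len(recipe.factors))))


def _invert_cdf(model_id, params, u):
    """Event time with conditional CDF F(t)/d = u, by closed form."""
    b, d, e = params["b"], params["d"], params["e"]
    u = np.asarray(u, dtype=float)
    if model_id == "TE_LL4":
        return e * (u / (1 - u)) ** (1.0 / b)
    if model_id == "TE_W":
        return e * (-np.log1p(-u)) ** (1.0 / b)
    if model_id == "TE_LN":
        from scipy import stats
        return e * np.exp(stats.norm.ppf(u) / b)
    raise KeyError(f"unknown TE model {model_id!r}")


def simulate_time_to_event(recipe: TERecipe) -> TimeToEventDataset:
    """Binomial responders, inverse-CDF event times, interval binning.

    Each individual responds with probability d; responders' event times
    follow the conditional distribution F(t)/d and are binned into the
    inspection intervals; non-responders and responders beyond the last
    inspection form the right-censored remainder.
    """
    rng = np.random.default_rng(recipe.seed)
    times = np.asarray(recipe.inspection_times, dtype=float)
    if np.any(np.diff(times) <= 0) or times[0] <= 0:
        raise ValueError("inspection_times must be positive and increasing")
    edges = np.concatenate([[0.0], times])
    records: list[TERecord] = []
    totals: dict = {}
    d = recipe.params["d"]
    for rep in range(1, recipe.replicates + 1):
        responder = rng.random(recipe.n_individuals) < d
        u = rng.random(int(responder.sum()))
        t = _invert_cdf(recipe.model_id, recipe.params, u)
        counts, _ = np.histogram(t, bins=np.concatenate([edges[:1], times]))
        for k in range(times.size):
            records.append(TERecord(recipe.factors, rep,
                                    float(edges[k]), float(edges[k + 1]),
                                    int(counts[k])))
        totals[(recipe.factors, rep)] = recipe.n_individuals
    ds = TimeToEventDataset(records, totals,
                            factor_names=tuple(
                                f"factor{i+1}"
                                for i in range(len(recipe.factors))))
    return ds.with_censored_remainder()
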