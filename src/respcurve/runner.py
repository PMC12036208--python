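"""End-to-end analysis runs: fit -> select -> estimate -> assess -> export.

One curve is analyzed per factor combination; results are collected into a
:class:`RunResult` whose tables mask out-of-range estimates, per the policy
that values beyond the tested dose range or time frame are not reported to
the user.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assessment import AssessmentReport, assess
from .datasets import (AnalysisConfig, DoseResponseDataset, TimeToEventDataset,
                       aggregate_by_dose)
from .effective_dose import (CapabilityError, EffectiveDoseEstimate,
                             NoSolutionError, biphasic_metrics, ed50_delta,
                             ed50_interpolation, ed50_reed_muench,
                             restrict_to_range, t50_estimate)
from .fitting import FitError, FittedCurve, select_best_model
from .models import list_candidate_models
from .te import TEFitError, fit_te_parametric, kde_smooth, turnbull_npmle

__all__ = ["CurveResult", "RunResult", "run_dr", "run_te"]


@dataclass
class CurveResult:
    curve_id: tuple[str, ...]
    fit: object | None
    estimates: list[EffectiveDoseEstimate] = field(default_factory=list)
    assessment: AssessmentReport | None = None
    metrics: object | None = None
    error: str = ""


@dataclass
class RunResult:
    curves: list[CurveResult]
    config: AnalysisConfig
    data_type: str
    version: str = __version__
    plot_paths: list[str] = field(default_factory=list)

    def estimates_table(self) -> pd.DataFrame:
        rows = []
        for cr in self.curves:
            for est in cr.estimates:
                rows.append({
                    "curve": "/".join(cr.curve_id), "kind": est.kind,
                    "basis": est.basis, "phase": est.phase,
                    "method": est.method,
                    "estimate": est.masked_value(),
                    "se": est.se if est.in_range and est.se is not None
                    else math.nan,
                    "ci_low": est.ci[0] if est.in_range and est.ci else math.nan,
                    "ci_high": est.ci[1] if est.in_range and est.ci else math.nan,
                    "in_range": est.in_range, "note": est.note})
        return pd.DataFrame(rows, columns=[
            "curve", "kind", "basis", "phase", "method", "estimate", "se",
            "ci_low", "ci_high", "in_range", "note"])

    def assessment_table(self) -> pd.DataFrame:
        rows = []
        for cr in self.curves:
            if cr.assessment is None:
                continue
            for r in cr.assessment.to_rows():
                rows.append({"curve": "/".join(cr.curve_id), **r})
        return pd.DataFrame(rows)

    def fits_json(self) -> str:
        payload = {"version": self.version,
                   "config": {k: (list(v) if isinstance(v, tuple) else v)
                              for k, v in vars(self.config).items()},
                   "curves": []}
        for cr in self.curves:
            entry = {"curve": "/".join(cr.curve_id), "error": cr.error}
            if cr.fit is not None and hasattr(cr.fit, "summary"):
                entry["fit"] = cr.fit.summary()
            payload["curves"].append(entry)
        return json.dumps(payload, indent=2, default=float)

    def export(self, out_dir) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        est = out / "estimates.csv"
        self.estimates_table().to_csv(est, index=False)
        paths["estimates"] = str(est)
        ass = self.assessment_table()
        if not ass.empty:
            p = out / "assessment.csv"
            ass.to_csv(p, index=False)
            paths["assessment"] = str(p)
        fits = out / "fits.json"
        fits.write_text(self.fits_json())
        paths["fits"] = str(fits)
        return paths


def _dr_estimates(fit: FittedCurve, ds_curve: DoseResponseDataset,
                  config: AnalysisConfig) -> list[EffectiveDoseEstimate]:
    basis = config.ed_basis
    level = (config.resolve_absolute_level(ds_curve.response_scale)
             if basis == "absolute" else 0.5)
    rng_range = (float(ds_curve.doses.min()), float(ds_curve.doses.max()))
    biphasic = fit.spec.shape_class == "biphasic"
    out: list[EffectiveDoseEstimate] = []
    if config.ed_method == "ritz_gerhard":
        phases = ["high"] if biphasic else ["single"]
        for ph in phases:
            try:
                out.append(ed50_delta(fit, basis, level, phase=ph,
                                      ci_level=config.ci_level))
            except NoSolutionError as exc:
                out.append(EffectiveDoseEstimate(
                    "ED50", basis, ph, "ritz_gerhard", math.nan,
                    in_range=False, level=level, note=str(exc)))
    elif config.ed_method == "serra_greco":
        out.extend(ed50_interpolation(fit, basis, level,
                                      ci_level=config.ci_level))
    else:  # reed_muench
        if basis != "absolute":
            raise CapabilityError(
                "the Reed-and-Muench method estimates absolute ED50 only")
        agg = aggregate_by_dose(ds_curve)
        try:
            out.append(ed50_reed_muench(agg, level, seed=config.seed,
                                        ci_level=config.ci_level,
                                        raw=ds_curve))
        except NoSolutionError as exc:
            out.append(EffectiveDoseEstimate(
                "ED50", basis, "single", "reed_muench", math.nan,
                in_range=False, level=level, note=str(exc)))
    return [restrict_to_range(e, rng_range) for e in out]


def run_dr(ds: DoseResponseDataset, config: AnalysisConfig) -> RunResult:
    """Full dose-response pipeline over every factor combination."""
    ds.validate_for_fitting()
    candidates = (list_candidate_models(ds.shape)
                  if config.candidate_models in ("all", None)
                  else config.candidate_models)
    curves: list[CurveResult] = []
    for fac in ds.curve_ids():
        sub = ds.subset(fac)
        try:
            fit = select_best_model(sub, candidates,
                                    config.selection_criterion,
                                    seed=config.seed)
            ests = _dr_estimates(fit, sub, config)
            report = assess(fit, sub)
            metrics = (biphasic_metrics(fit, config.ci_level)
                       if fit.spec.shape_class == "biphasic" else None)
            curves.append(CurveResult(fac, fit, ests, report, metrics))
        except (FitError, CapabilityError) as exc:
            if isinstance(exc, CapabilityError):
                raise
            curves.append(CurveResult(fac, None, error=str(exc)))
    return RunResult(curves, config, "DR")


def run_te(ds: TimeToEventDataset, config: AnalysisConfig,
           models: list[str] | None = None,
           nonparametric: bool = True) -> RunResult:
    """Full time-to-event pipeline: parametric fits (best by criterion),
    NPMLE (+ KDE) per curve, absolute and relative T50."""
    from .te import TE_MODELS
    models = models or list(TE_MODELS)
    curves: list[CurveResult] = []
    for fac in ds.curve_ids():
        sub = ds.subset(fac)
        triples = sub.pooled_intervals()
        finite = [t for t in triples if math.isfinite(t[1]) and t[2] > 0]
        t_range = (0.0, max((t[1] for t in finite), default=0.0))
        fits = []
        errors = []
        for mid in models:
            try:
                f = fit_te_parametric(sub, mid)
                crit = f.aic if config.selection_criterion == "AIC" else f.bic
                fits.append((crit, f))
            except TEFitError as exc:
                errors.append(f"{mid}: {exc}")
        ests: list[EffectiveDoseEstimate] = []
        best = None
        if fits:
            fits.sort(key=lambda t: t[0])
            best = fits[0][1]
            for basis in ("absolute", "relative"):
                ests.append(t50_estimate(best, basis,
                                         ci_level=config.ci_level,
                                         time_range=t_range))
        if nonparametric:
            try:
                np_fit = turnbull_npmle(sub)
                for basis in ("absolute", "relative"):
                    ests.append(t50_estimate(np_fit, basis,
                                             time_range=t_range))
                smooth = kde_smooth(np_fit)
                for basis in ("absolute", "relative"):
                    ests.append(t50_estimate(smooth, basis,
                                             time_range=t_range))
            except TEFitError as exc:
                errors.append(f"npmle: {exc}")
        curves.append(CurveResult(fac, best, ests,
                                  error="; ".join(errors)))
    return RunResult(curves, config, "TE")
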