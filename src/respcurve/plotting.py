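"""Publication-style plots: fitted curves, replicate means, and dashed
estimate/CI guides.

The dose axis is log-scaled; an untreated control (dose 0) cannot sit on a
log axis, so it is drawn at a pseudo-position below the smallest nonzero
dose with an axis-break marker, rather than being dropped.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")  # headless backend; figures go straight to files
matplotlib.rcParams["svg.hashsalt"] = "respcurve"  # reproducible SVG ids
import matplotlib.pyplot as plt
import numpy as np

from .datasets import DoseResponseDataset, aggregate_by_dose

__all__ = ["render_dr_plot", "render_te_plot", "render_plot"]


def _pseudo_zero(doses: np.ndarray, factor: float = 10.0) -> float:
    pos = doses[doses > 0]
    return float(pos.min() / factor) if pos.size else 1.0


def render_dr_plot(result, ds: DoseResponseDataset, path,
                   pseudo_zero_factor: float = 10.0,
                   formats: tuple[str, ...] = ("png",)) -> list[str]:
    """Dose-response panel per curve: means +/- SD, fitted line, dashed
    vertical lines at in-range estimates and their CI edges."""
    agg = aggregate_by_dose(ds)
    curves = [c for c in result.curves if c.fit is not None]
    if not curves:
        raise ValueError("nothing fitted: no curves to draw")
    ncol = min(len(curves), 2)
    nrow = math.ceil(len(curves) / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(5.2 * ncol, 3.8 * nrow),
                             squeeze=False)
    fnames = list(ds._fnames())
    for ax in axes.ravel()[len(curves):]:
        ax.set_visible(False)
    for ax, cr in zip(axes.ravel(), curves):
        sub = ds.subset(cr.curve_id)
        doses = sub.doses
        p0 = _pseudo_zero(doses, pseudo_zero_factor)
        if fnames:
            mask = np.ones(len(agg), dtype=bool)
            for name, val in zip(fnames, cr.curve_id):
                mask &= (agg[name].astype(str) == val).to_numpy()
            sub_agg = agg[mask]
        else:
            sub_agg = agg
        x = sub_agg["dose"].to_numpy(dtype=float)
        xp = np.where(x == 0, p0, x)
        ax.errorbar(xp, sub_agg["mean"], yerr=sub_agg["sd"].fillna(0.0),
                    fmt="o", ms=4, capsize=2, color="black", lw=1)
        pos = doses[doses > 0]
        grid = np.geomspace(max(pos.min(), p0), doses.max(), 400)
        grid_full = np.concatenate([[0.0], grid])
        y = np.asarray(cr.fit.predict(grid_full))
        ax.plot(np.concatenate([[p0], grid]), y, color="tab:blue", lw=1.5)
        for est in cr.estimates:
            if not est.in_range or not math.isfinite(est.value):
                continue  # masked estimates draw nothing
            ax.axvline(est.value, ls="--", lw=1, color="tab:red")
            if est.ci:
                for edge in est.ci:
                    if edge > 0:
                        ax.axvline(edge, ls="--", lw=0.6, color="tab:red",
                                   alpha=0.5)
        ax.set_xscale("log")
        if (doses == 0).any():
            ax.annotate("//", xy=(p0, 0), xycoords=("data", "axes fraction"),
                        ha="center", va="top", fontsize=9,
                        annotation_clip=False)
        ax.set_xlabel("dose")
        ax.set_ylabel("response")
        ax.set_title("/".join(cr.curve_id), fontsize=10)
    fig.tight_layout()
    return _save(fig, path, formats)


def render_te_plot(result, ds, path,
                   formats: tuple[str, ...] = ("png",)) -> list[str]:
    """Time-to-event panel per curve: observed cumulative fractions, fitted
    CDF, dashed lines at in-range T50 estimates."""
    curves = result.curves
    if not any(c.fit is not None or c.estimates for c in curves):
        raise ValueError("nothing fitted: no curves to draw")
    ncol = min(len(curves), 2)
    nrow = math.ceil(len(curves) / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(5.2 * ncol, 3.8 * nrow),
                             squeeze=False)
    for ax in axes.ravel()[len(curves):]:
        ax.set_visible(False)
    for ax, cr in zip(axes.ravel(), curves):
        sub = ds.subset(cr.curve_id)
        triples = [t for t in sub.pooled_intervals() if math.isfinite(t[1])]
        total = sum(v for (_, r), v in
                    [((a, b), n) for a, b, n in sub.pooled_intervals()])
        if triples and total > 0:
            ts = np.array([r for _, r, _ in triples])
            cum = np.cumsum([n for _, _, n in triples]) / total
            ax.step(ts, cum, where="post", color="black", lw=1,
                    label="observed")
            ax.plot(ts, cum, "o", ms=3, color="black")
        if cr.fit is not None:
            grid = np.linspace(0, max((r for _, r, _ in triples),
                                      default=1.0), 400)
            ax.plot(grid, np.asarray(cr.fit.cdf(grid)), color="tab:blue",
                    lw=1.5, label=cr.fit.model_id)
        for est in cr.estimates:
            if est.in_range and math.isfinite(est.value):
                ax.axvline(est.value, ls="--", lw=1, color="tab:red")
        ax.axhline(0.5, ls=":", lw=0.8, color="grey")
        ax.set_ylim(0, 1.02)
        ax.set_xlabel("time")
        ax.set_ylabel("cumulative fraction")
        ax.set_title("/".join(cr.curve_id), fontsize=10)
    fig.tight_layout()
    return _save(fig, path, formats)


def _save(fig, path, formats) -> list[str]:
    from pathlib import Path
    base = Path(path)
    out = []
    for fmt in formats:
        p = base.with_suffix(f".{fmt}")
        fig.savefig(p, dpi=150, metadata=_stable_metadata(fmt))
        out.append(str(p))
    plt.close(fig)
    return out


def _stable_metadata(fmt):
    # fixed metadata so repeated renders of the same result are
    # byte-identical (SVG embeds a date by default)
    if fmt == "svg":
        return {"Date": None}
    if fmt == "png":
        return {"Software": None}
    return None


def render_plot(result, ds, path, formats=("png", "svg"), **kw) -> list[str]:
    """Dispatch on the result's data type."""
    if result.data_type == "DR":
        return render_dr_plot(result, ds, path, formats=formats, **kw)
    return render_te_plot(result, ds, path, formats=formats)
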