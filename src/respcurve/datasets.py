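"""Tidy data containers, readers/writers, validation and aggregation.

Two experiment types are supported:

* dose-response (DR): replicated (factors, dose, response) records, with a
  user-declared curve shape (monotonic or biphasic);
* time-to-event (TE): interval-censored counts -- the number of events
  (e.g. germinated seeds) observed inside each inspection interval
  ``(time_before, time_after]``, with right censoring encoded as
  ``time_after = inf``.

Factor combinations identify independent curves and are analyzed one curve
at a time throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DRRecord",
    "TERecord",
    "DoseResponseDataset",
    "TimeToEventDataset",
    "AnalysisConfig",
    "SchemaError",
    "ValidationError",
    "read_tidy_table",
    "write_tidy_table",
    "normalize_to_control",
    "aggregate_by_dose",
]


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class ValidationError(ValueError):
    """Parsed values violate the data-model invariants."""


@dataclass(frozen=True)
class DRRecord:
    factors: tuple[str, ...]
    replicate: int
    dose: float
    response: float


@dataclass(frozen=True)
class TERecord:
    factors: tuple[str, ...]
    replicate: int
    time_before: float
    time_after: float  # math.inf encodes right censoring
    count: int


@dataclass
class DoseResponseDataset:
    """Tidy replicated dose-response records for one or more curves."""

    records: list[DRRecord]
    shape: str = "monotonic"  # monotonic | biphasic
    response_scale: str = "raw"  # percent | proportion | raw
    factor_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.shape not in ("monotonic", "biphasic"):
            raise ValidationError(f"unknown shape {self.shape!r}")
        if self.response_scale not in ("percent", "proportion", "raw"):
            raise ValidationError(f"unknown response_scale {self.response_scale!r}")
        for i, r in enumerate(self.records):
            if r.dose < 0:
                raise ValidationError(f"negative dose at record {i}: {r.dose}")
            if not math.isfinite(r.response):
                raise ValidationError(f"non-finite response at record {i}")
            if r.replicate < 1:
                raise ValidationError(f"replicate must be >= 1 at record {i}")

    # -- views -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {**{n: v for n, v in zip(self._fnames(), r.factors)},
             "replicate": r.replicate, "dose": r.dose, "response": r.response}
            for r in self.records
        ]
        cols = [*self._fnames(), "replicate", "dose", "response"]
        return pd.DataFrame(rows, columns=cols)

    def _fnames(self) -> tuple[str, ...]:
        if self.factor_names:
            return self.factor_names
        width = len(self.records[0].factors) if self.records else 0
        return tuple(f"factor{i + 1}" for i in range(width))

    def curve_ids(self) -> list[tuple[str, ...]]:
        seen: dict[tuple[str, ...], None] = {}
        for r in self.records:
            seen.setdefault(r.factors, None)
        return list(seen)

    def subset(self, factors: tuple[str, ...]) -> "DoseResponseDataset":
        return replace(self, records=[r for r in self.records if r.factors == factors])

    @property
    def doses(self) -> np.ndarray:
        return np.array([r.dose for r in self.records])

    @property
    def responses(self) -> np.ndarray:
        return np.array([r.response for r in self.records])

    def distinct_doses(self) -> np.ndarray:
        return np.unique(self.doses)

    def validate_for_fitting(self) -> None:
        for fac in self.curve_ids():
            sub = self.subset(fac)
            if len(sub.distinct_doses()) < 3:
                raise ValidationError(
                    f"curve {fac}: at least 3 distinct doses required, "
                    f"got {len(sub.distinct_doses())}"
                )


@dataclass
class TimeToEventDataset:
    """Interval-censored event counts, one set of intervals per replicate."""

    records: list[TERecord]
    group_totals: dict[tuple[tuple[str, ...], int], int] = field(default_factory=dict)
    factor_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for i, r in enumerate(self.records):
            if r.time_before < 0:
                raise ValidationError(f"negative time_before at record {i}")
            if not r.time_before < r.time_after:
                raise ValidationError(
                    f"record {i}: time_before ({r.time_before}) must be < "
                    f"time_after ({r.time_after})"
                )
            if r.count < 0:
                raise ValidationError(f"negative count at record {i}")
        self._check_overlap()
        self._check_totals()

    def _check_overlap(self) -> None:
        by_rep: dict[tuple, list[TERecord]] = {}
        for r in self.records:
            by_rep.setdefault((r.factors, r.replicate), []).append(r)
        for key, recs in by_rep.items():
            finite = sorted((r for r in recs if math.isfinite(r.time_after)),
                            key=lambda r: (r.time_before, r.time_after))
            for a, b in zip(finite, finite[1:]):
                if b.time_before < a.time_after:
                    raise ValidationError(
                        f"overlapping intervals for group {key}: "
                        f"({a.time_before},{a.time_after}] and "
                        f"({b.time_before},{b.time_after}]"
                    )

    def _check_totals(self) -> None:
        for key, total in self.group_totals.items():
            if total <= 0:
                raise ValidationError(f"group_total must be positive for {key}")
            s = sum(r.count for r in self.records
                    if (r.factors, r.replicate) == key)
            if s > total:
                raise ValidationError(
                    f"counts for group {key} sum to {s} > group_total {total}"
                )

    def curve_ids(self) -> list[tuple[str, ...]]:
        seen: dict[tuple[str, ...], None] = {}
        for r in self.records:
            seen.setdefault(r.factors, None)
        return list(seen)

    def subset(self, factors: tuple[str, ...]) -> "TimeToEventDataset":
        return TimeToEventDataset(
            records=[r for r in self.records if r.factors == factors],
            group_totals={k: v for k, v in self.group_totals.items()
                          if k[0] == factors},
            factor_names=self.factor_names,
        )

    def with_censored_remainder(self) -> "TimeToEventDataset":
        """Synthesize the right-censored row for every group whose counts
        fall short of its total; leaves groups without a declared total
        untouched."""
        extra: list[TERecord] = []
        for (fac, rep), total in self.group_totals.items():
            recs = [r for r in self.records if (r.factors, r.replicate) == (fac, rep)]
            observed = sum(r.count for r in recs)
            if observed < total:
                last = max((r.time_after for r in recs
                            if math.isfinite(r.time_after)), default=0.0)
                extra.append(TERecord(fac, rep, last, math.inf, total - observed))
        return TimeToEventDataset(self.records + extra, dict(self.group_totals),
                                  self.factor_names)

    def pooled_intervals(self) -> list[tuple[float, float, int]]:
        """Replicate-pooled (time_before, time_after, count) triples."""
        acc: dict[tuple[float, float], int] = {}
        for r in self.records:
            key = (r.time_before, r.time_after)
            acc[key] = acc.get(key, 0) + r.count
        return sorted(((lo, hi, n) for (lo, hi), n in acc.items()),
                      key=lambda t: (t[0], t[1]))

    def to_frame(self) -> pd.DataFrame:
        fnames = self.factor_names or tuple(
            f"factor{i + 1}"
            for i in range(len(self.records[0].factors) if self.records else 0))
        rows = []
        for r in self.records:
            total = self.group_totals.get((r.factors, r.replicate), np.nan)
            rows.append({**{n: v for n, v in zip(fnames, r.factors)},
                         "replicate": r.replicate,
                         "time_before": r.time_before,
                         "time_after": r.time_after,
                         "count": r.count, "total": total})
        return pd.DataFrame(rows, columns=[*fnames, "replicate", "time_before",
                                           "time_after", "count", "total"])


ED_METHODS = ("ritz_gerhard", "serra_greco", "reed_muench")


@dataclass
class AnalysisConfig:
    """Options driving a full dose-response or time-to-event run."""

    data_type: str = "DR"  # DR | TE
    candidate_models: list[str] | str = "all"
    selection_criterion: str = "AIC"  # AIC | BIC
    ed_basis: str = "relative"  # absolute | relative
    absolute_level: float | None = None  # default depends on response scale
    ed_method: str = "ritz_gerhard"
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.data_type not in ("DR", "TE"):
            raise ValidationError(f"data_type must be DR or TE, got {self.data_type!r}")
        if self.selection_criterion not in ("AIC", "BIC"):
            raise ValidationError("selection_criterion must be AIC or BIC")
        if self.ed_basis not in ("absolute", "relative"):
            raise ValidationError("ed_basis must be absolute or relative")
        if self.ed_method not in ED_METHODS:
            raise ValidationError(f"ed_method must be one of {ED_METHODS}")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must lie in (0, 1)")

    def resolve_absolute_level(self, response_scale: str) -> float:
        if self.absolute_level is not None:
            return self.absolute_level
        return 0.5 if response_scale == "proportion" else 50.0


# ---------------------------------------------------------------------------
# readers / writers

_DR_DEFAULT_MAP = {"replicate": "replicate", "dose": "dose", "response": "response"}
_TE_DEFAULT_MAP = {"replicate": "replicate", "time_before": "time_before",
                   "time_after": "time_after", "count": "count", "total": "total"}


def _load_frame(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        return pd.read_csv(path, sep="\t")
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _require_numeric(frame, col, kind=float):
    vals = pd.to_numeric(frame[col], errors="coerce")
    bad = vals.isna() & frame[col].notna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"column {col!r}: non-numeric value {frame[col].iloc[idx]!r} at row {idx}"
        )
    if vals.isna().any():
        idx = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise ValidationError(f"column {col!r}: missing value at row {idx}")
    return vals.astype(kind)


def read_tidy_table(path, data_type: str, schema_map: dict[str, str] | None = None,
                    factor_columns: list[str] | None = None,
                    shape: str = "monotonic"):
    """Read a tidy CSV/TSV (or Excel) table into a validated dataset.

    ``schema_map`` maps canonical field names (``dose``, ``response``,
    ``replicate``, ``time_before``, ``time_after``, ``count``, ``total``) to
    the column names actually present in the file.  Columns not mentioned in
    ``schema_map`` or ``factor_columns`` are treated as factor columns.
    For TE data the right-censored remainder row is synthesized whenever the
    recorded counts fall short of the declared group total.
    """
    frame = _load_frame(path)
    default = _DR_DEFAULT_MAP if data_type == "DR" else _TE_DEFAULT_MAP
    cmap = {**default, **(schema_map or {})}
    missing = [v for k, v in cmap.items() if v not in frame.columns and k != "total"]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    mapped = set(cmap.values())
    if factor_columns is None:
        factor_columns = [c for c in frame.columns if c not in mapped]
    fnames = tuple(factor_columns)

    reps = _require_numeric(frame, cmap["replicate"], int)
    factors = [tuple(str(frame[c].iloc[i]) for c in factor_columns)
               for i in range(len(frame))]

    if data_type == "DR":
        doses = _require_numeric(frame, cmap["dose"])
        resp = _require_numeric(frame, cmap["response"])
        records = [DRRecord(factors[i], int(reps.iloc[i]),
                            float(doses.iloc[i]), float(resp.iloc[i]))
                   for i in range(len(frame))]
        return DoseResponseDataset(records, shape=shape, factor_names=fnames)

    lo = _require_numeric(frame, cmap["time_before"])
    hi = frame[cmap["time_after"]].replace({"Inf": np.inf, "inf": np.inf})
    hi = pd.to_numeric(hi, errors="coerce")
    if hi.isna().any():
        idx = int(np.flatnonzero(hi.isna().to_numpy())[0])
        raise ValidationError(f"column {cmap['time_after']!r}: bad value at row {idx}")
    counts = _require_numeric(frame, cmap["count"], int)
    records = [TERecord(factors[i], int(reps.iloc[i]), float(lo.iloc[i]),
                        float(hi.iloc[i]), int(counts.iloc[i]))
               for i in range(len(frame))]
    totals: dict[tuple[tuple[str, ...], int], int] = {}
    if cmap.get("total") in frame.columns:
        tot = _require_numeric(frame, cmap["total"], int)
        for i in range(len(frame)):
            totals[(factors[i], int(reps.iloc[i]))] = int(tot.iloc[i])
    ds = TimeToEventDataset(records, totals, fnames)
    return ds.with_censored_remainder()


def write_tidy_table(ds, path) -> None:
    """Write a dataset back to CSV (TSV if the suffix says so)."""
    frame = ds.to_frame()
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    frame.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# transformations

def normalize_to_control(ds: DoseResponseDataset,
                         control_dose: float = 0.0) -> DoseResponseDataset:
    """Express responses as percent of the per-curve mean control response.

    Absolute ED50 values are only meaningful on a control-normalized scale;
    this rescales each curve so the mean response at ``control_dose`` is 100.
    Idempotent: normalizing an already-percent dataset leaves it unchanged
    up to the same ratio transform.
    """
    new: list[DRRecord] = []
    for fac in ds.curve_ids():
        sub = [r for r in ds.records if r.factors == fac]
        ctrl = [r.response for r in sub if r.dose == control_dose]
        if not ctrl:
            raise ValidationError(
                f"curve {fac}: control dose {control_dose} absent; absolute "
                "normalization impossible -- use relative ED50 instead"
            )
        mean = float(np.mean(ctrl))
        if mean == 0:
            raise ValidationError(f"curve {fac}: mean control response is zero")
        new.extend(replace(r, response=100.0 * r.response / mean) for r in sub)
    return replace(ds, records=new, response_scale="percent")


def aggregate_by_dose(ds: DoseResponseDataset) -> pd.DataFrame:
    """Per-(curve, dose) mean, SD and replicate count.

    SD is NaN when a cell holds a single observation.
    """
    frame = ds.to_frame()
    if frame.empty:
        return pd.DataFrame(columns=[*ds._fnames(), "dose", "mean", "sd", "n"])
    fnames = list(ds._fnames())
    grouped = (frame.groupby([*fnames, "dose"], sort=True)["response"]
               .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
               .reset_index())
    return grouped
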