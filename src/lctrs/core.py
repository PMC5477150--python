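"""Domain types and closed-form quantities of two-reference retention calibration.

The central object is the *standard retention time* St_R: the arithmetic mean
of one compound's retention time measured on a panel of chromatographic
columns run under a single fixed elution program.  Because retention times of
the same compounds on two different reversed-phase systems are, to a very good
approximation, related by an affine map, each column's measured times are an
affine function of St_R as well.  Two reference substances injected on a new
target column therefore suffice to place every other compound: the line
through the two reference points maps the consensus St_R axis onto the target
column's time axis.

This module holds the data containers shared by the rest of the package and
the four closed-form quantities the method rests on:

* :func:`compute_strt` — the St_R consensus (per-compound mean over columns);
* :func:`delta_tr` — the |measured − predicted| deviation used for scoring;
* :func:`coverage_of_tr` — the fraction of the panel's retention span
  bracketed by a candidate reference pair;
* :func:`calibrated_retention` — the dimensionless position of an analyte
  between the two references on the St_R axis (equivalent to two-point
  interpolation, and to relative retention when the anchor is the origin).

All retention times are in minutes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RetentionTable",
    "StandardRetention",
    "CalibrationLine",
    "ReferencePair",
    "MatchConfig",
    "PeakList",
    "compute_strt",
    "delta_tr",
    "coverage_of_tr",
    "calibrated_retention",
    "make_reference_pair",
]


@dataclass(frozen=True)
class CalibrationLine:
    """Affine map ``t_R = slope * St_R + intercept`` fitted on one column.

    ``r`` is the Pearson correlation of the fitted points; it is ``None`` for
    two-point fits, where the line interpolates both points by construction.
    ``method`` tags how the line was obtained (``"two_point"`` or
    ``"least_squares"``).
    """

    slope: float
    intercept: float
    r: float | None = None
    method: str = "least_squares"

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope) or not math.isfinite(self.intercept):
            raise ValueError("calibration line coefficients must be finite")
        if self.r is not None and abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")

    def __call__(self, st_r: float) -> float:
        return self.slope * st_r + self.intercept


class RetentionTable:
    """Measured retention times of K compounds on N columns (minutes).

    Parameters
    ----------
    times
        DataFrame indexed by compound identifier with one column per
        chromatographic column identifier.  Cells are retention times in
        minutes; NaN marks a missing measurement (such columns must be
        excluded before computing St_R).
    sd
        Optional DataFrame of the same shape holding injection-replicate
        standard deviations, minutes.
    """

    def __init__(self, times: pd.DataFrame, sd: pd.DataFrame | None = None):
        times = pd.DataFrame(times).astype(float)
        if times.index.has_duplicates:
            dupes = times.index[times.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate compound identifiers: {dupes}")
        if times.columns.has_duplicates:
            dupes = times.columns[times.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate column identifiers: {dupes}")
        bad = (times <= 0) | np.isinf(times)
        if bad.any().any():
            comp = times.index[bad.any(axis=1)][0]
            col = times.columns[bad.loc[comp]][0]
            raise ValueError(
                f"retention times must be finite and > 0; offending cell "
                f"({comp!r}, {col!r}) = {times.loc[comp, col]}"
            )
        if sd is not None:
            sd = pd.DataFrame(sd).astype(float).reindex(index=times.index, columns=times.columns)
            if (sd < 0).any().any():
                raise ValueError("standard deviations must be >= 0")
        self.times = times
        self.sd = sd

    @property
    def compounds(self) -> list[str]:
        return list(self.times.index)

    @property
    def columns(self) -> list[str]:
        return list(self.times.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.times.shape

    def complete_columns(self) -> list[str]:
        """Columns with a measurement for every compound."""
        return list(self.times.columns[self.times.notna().all(axis=0)])

    def subset(
        self,
        compounds: Iterable[str] | None = None,
        columns: Iterable[str] | None = None,
    ) -> "RetentionTable":
        t = self.times
        if compounds is not None:
            compounds = list(compounds)
            missing = set(compounds) - set(t.index)
            if missing:
                raise KeyError(f"unknown compounds: {sorted(missing)}")
            t = t.loc[compounds]
        if columns is not None:
            columns = list(columns)
            missing = set(columns) - set(t.columns)
            if missing:
                raise KeyError(f"unknown columns: {sorted(missing)}")
            t = t[columns]
        sd = None
        if self.sd is not None:
            sd = self.sd.loc[t.index, t.columns]
        return RetentionTable(t, sd)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        k, n = self.shape
        return f"RetentionTable({k} compounds x {n} columns)"


@dataclass(frozen=True)
class StandardRetention:
    """Per-compound standard retention times and the columns they average.

    ``values`` is a Series indexed by compound (minutes); ``columns_used`` is
    the set of column identifiers that entered the mean; ``n`` their count.
    """

    values: pd.Series
    columns_used: frozenset
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("St_R requires at least one column")
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("St_R values must be finite and positive")

    def __getitem__(self, compound: str) -> float:
        return float(self.values[compound])

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    def ordered(self) -> pd.Series:
        """Values sorted ascending — the elution order on the consensus axis."""
        return self.values.sort_values()


@dataclass(frozen=True)
class ReferencePair:
    """Two reference compounds bracketing the analytes on the St_R axis.

    ``first`` has the smaller St_R, ``second`` the larger; ``coverage`` is the
    fraction of the panel's retention span the pair brackets (0, 1].
    """

    first: str
    second: str
    coverage: float

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise ValueError("reference pair must be two distinct compounds")
        if not 0 <= self.coverage <= 1 + 1e-12:
            raise ValueError(f"coverage must lie in [0, 1], got {self.coverage}")


@dataclass(frozen=True)
class MatchConfig:
    """Peak-matching tolerances, minutes.

    ``t_r_window`` (the search window around a predicted time) is set larger
    than ``t_r_limit`` (the pass/fail deviation limit after multi-point
    validation) so that a peak slightly off the first prediction can still be
    found, then vetted by the regression stage.  Recommended working ranges
    are 0.8–2.0 min for the window and 0.5–1.5 min for the limit; both may be
    overridden per compound when individual peaks are known to drift more.
    ``series_gap`` is the closeness threshold below which neighbouring
    predictions sharing a candidate peak are treated as one series and matched
    in elution order rather than each by least deviation.
    """

    t_r_window: float = 1.2
    t_r_limit: float = 0.5
    series_gap: float = 2.0
    window_overrides: Mapping[str, float] = field(default_factory=dict)
    limit_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.t_r_limit > 0:
            raise ValueError("t_r_limit must be > 0")
        if self.t_r_window < self.t_r_limit:
            raise ValueError("t_r_window must be >= t_r_limit")
        if not self.series_gap > 0:
            raise ValueError("series_gap must be > 0")
        for name, v in {**dict(self.window_overrides), **dict(self.limit_overrides)}.items():
            if not v > 0:
                raise ValueError(f"override for {name!r} must be > 0, got {v}")

    def window_for(self, compound: str) -> float:
        return float(self.window_overrides.get(compound, self.t_r_window))

    def limit_for(self, compound: str) -> float:
        return float(self.limit_overrides.get(compound, self.t_r_limit))


@dataclass(frozen=True)
class PeakList:
    """Observed peak retention times of one chromatogram, strictly increasing."""

    times: tuple
    labels: tuple | None = None

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        object.__setattr__(self, "times", t)
        if any(x <= 0 for x in t):
            raise ValueError("peak retention times must be > 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("peak retention times must be strictly increasing")
        if self.labels is not None and len(self.labels) != len(t):
            raise ValueError("labels must parallel peak times")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        return iter(self.times)


def compute_strt(
    table: RetentionTable, included: Iterable[str] | None = None
) -> StandardRetention:
    """Standard retention time: per-compound mean over the included columns.

    Parameters
    ----------
    table
        The K×N retention table.
    included
        Column identifiers to average over (default: all columns of the
        table).  Every included column must have a measurement for every
        compound; a column missing any compound must be excluded, not imputed.
    """
    cols = table.columns if included is None else list(included)
    if len(cols) == 0:
        raise ValueError("cannot compute St_R from an empty column set")
    unknown = set(cols) - set(table.columns)
    if unknown:
        raise KeyError(f"unknown columns: {sorted(unknown)}")
    sub = table.times[cols]
    incomplete = sub.columns[sub.isna().any(axis=0)]
    if len(incomplete):
        raise ValueError(
            f"column {incomplete[0]!r} is missing a measurement; exclude it "
            "before computing St_R"
        )
    values = sub.mean(axis=1)
    values.name = "st_r_min"
    return StandardRetention(values=values, columns_used=frozenset(cols), n=len(cols))


def delta_tr(t_mea: float, t_pre: float) -> float:
    """Absolute deviation |t_mea − t_pre| between measured and predicted time."""
    if not (math.isfinite(t_mea) and math.isfinite(t_pre)):
        raise ValueError("retention times must be finite")
    return abs(t_mea - t_pre)


def _span(strt: StandardRetention) -> float:
    v = strt.values
    if len(v) < 2:
        raise ValueError("coverage needs at least two compounds")
    span = float(v.max() - v.min())
    if span == 0:
        raise ValueError("all compounds co-elute on the consensus axis; coverage undefined")
    return span


def coverage_of_tr(
    strt: StandardRetention, first: str, second: str
) -> float:
    """Fraction of the panel's St_R span bracketed by a candidate pair.

    Equals 1 when the pair is the first- and last-eluting compound, and 0 for
    a degenerate pair with equal St_R (such a pair is invalid as a reference
    pair).  High coverage (80–100 %) is preferred when selecting references.
    """
    span = _span(strt)
    return abs(strt[second] - strt[first]) / span


def make_reference_pair(
    strt: StandardRetention, a: str, b: str
) -> ReferencePair:
    """Order two compounds by St_R and attach their coverage."""
    sa, sb = strt[a], strt[b]
    if sa == sb:
        raise ValueError(f"degenerate reference pair: {a!r} and {b!r} share St_R = {sa}")
    first, second = (a, b) if sa < sb else (b, a)
    return ReferencePair(first=first, second=second, coverage=coverage_of_tr(strt, first, second))


def calibrated_retention(
    strt: StandardRetention, pair: ReferencePair, analyte: str
) -> float:
    """Dimensionless position of an analyte between the two references.

    ``CR = (St_R(analyte) − St_R(first)) / (St_R(second) − St_R(first))`` —
    0 at the first reference, 1 at the second.  Predicting
    ``t_first + CR·(t_second − t_first)`` on a target column is algebraically
    identical to the two-point calibration line; relative retention is the
    special case whose anchor point is the origin (or the dead time).
    """
    denom = strt[pair.second] - strt[pair.first]
    if denom == 0:
        raise ValueError("degenerate reference pair")
    return (strt[analyte] - strt[pair.first]) / denom
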