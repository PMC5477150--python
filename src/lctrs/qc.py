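"""Panel quality control: outlier screening, reference selection, subsampling.

A retention panel is only as good as its linearity: each column's measured
times should be an affine function of the consensus St_R axis.  Columns whose
packing or hardware breaks that linearity (correlation below ~0.99, residuals
beyond 1–2 min) and compounds whose retention behaviour deviates from the
rest of the panel (e.g. structurally unrelated analytes) are excluded before
the final St_R is computed.  The same per-column fits drive the choice of the
two reference compounds and the study of how many columns a usable St_R
consensus actually needs.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import fit_least_squares, fit_two_point
from .core import (
    CalibrationLine,
    RetentionTable,
    StandardRetention,
    compute_strt,
    coverage_of_tr,
    make_reference_pair,
)

__all__ = [
    "ColumnFit",
    "ExclusionReport",
    "SubsampleSummary",
    "fit_column_vs_strt",
    "detect_outliers",
    "select_reference_pair",
    "subsample_study",
]


@dataclass(frozen=True)
class ColumnFit:
    """Least-squares fit of one column's measured times on St_R."""

    column: str
    line: CalibrationLine
    residuals: pd.Series  # per-compound |t_mea - fitted|, minutes
    r: float | None

    @property
    def max_residual(self) -> float:
        return float(self.residuals.max())


@dataclass(frozen=True)
class ExclusionReport:
    """Outcome of one screening pass over a panel.

    Maps excluded identifiers to human-readable reasons; ``final_strt`` is the
    consensus recomputed from the retained columns and compounds only.
    """

    excluded_columns: Mapping[str, str]
    excluded_compounds: Mapping[str, str]
    retained_columns: tuple
    retained_compounds: tuple
    final_strt: StandardRetention
    fits: Mapping[str, ColumnFit]


@dataclass(frozen=True)
class SubsampleSummary:
    """Mean ± sd of the regression deviation per consensus-panel size k."""

    table: pd.DataFrame  # index k; columns n_draws, mean_dtr, sd_dtr
    seed: int


def fit_column_vs_strt(
    table: RetentionTable, strt: StandardRetention, column: str
) -> ColumnFit:
    """Fit one column's measured times on the consensus St_R axis."""
    common = [c for c in table.compounds if c in strt.compounds]
    y = table.times.loc[common, column].dropna()
    if len(y) < 2:
        raise ValueError(f"column {column!r}: need >= 2 compounds to fit")
    x = strt.values[y.index]
    line = fit_least_squares(x.to_numpy(), y.to_numpy())
    fitted = line.slope * x + line.intercept
    residuals = (y - fitted).abs()
    residuals.name = column
    return ColumnFit(column=column, line=line, residuals=residuals, r=line.r)


def _fit_all(table: RetentionTable, strt: StandardRetention) -> dict:
    return {c: fit_column_vs_strt(table, strt, c) for c in table.complete_columns()}


def _robust_consensus(x: np.ndarray, Y: np.ndarray, iterations: int = 3) -> np.ndarray:
    """Contamination-resistant consensus axis for screening.

    The plain mean consensus is itself distorted by the outliers the screen
    is trying to find (a shuffled column or a minority-offset compound feeds
    straight into the mean).  Back-projecting each column through its own
    fitted affine map and taking the per-compound *median* across columns
    removes the harmless column-to-column affine variation first, so the
    median sees i.i.d. estimates of the same consensus value and shrugs off
    a minority of contaminated columns.
    """
    x = np.asarray(x, float).copy()
    for _ in range(iterations):
        xm = float(x.mean())
        dx = x - xm
        sxx = float(dx @ dx)
        if sxx == 0:
            return x
        a = dx @ (Y - Y.mean(axis=0)) / sxx
        b = Y.mean(axis=0) - a * xm
        usable = np.abs(a) > 0.2  # a near-zero slope makes back-projection blow up
        if not usable.any():
            return x
        z = (Y[:, usable] - b[usable]) / a[usable]
        x = np.median(z, axis=1)
    return x


def _column_outlier_candidate(x: np.ndarray, y: np.ndarray, resid_max: float) -> int | None:
    """Index of one column's outlier-candidate compound, or None.

    Trimmed-fit screen: of all leave-one-compound-out lines, the one with the
    smallest residual sum of squares is the column's clean fit; the compound
    it leaves out is the outlier candidate when its deviation from that clean
    line exceeds ``resid_max``.  Deciding per column via the trimmed fit is
    robust where raw residuals are not: an offset compound at high leverage
    shrinks its own residual and inflates its neighbours'.
    """
    K = len(x)
    if K < 4:  # leave-one-out line needs >= 3 clean points to be informative
        return None
    best: tuple | None = None
    for i in range(K):
        mask = np.ones(K, bool)
        mask[i] = False
        xi, yi = x[mask], y[mask]
        dx = xi - xi.mean()
        sxx = float(dx @ dx)
        if sxx == 0:
            continue
        a = float(dx @ (yi - yi.mean())) / sxx
        b = float(yi.mean()) - a * float(xi.mean())
        sse = float(((yi - a * xi - b) ** 2).sum())
        dev = abs(float(y[i]) - (a * float(x[i]) + b))
        if best is None or sse < best[0]:
            best = (sse, i, dev)
    if best is not None and best[2] > resid_max:
        return int(best[1])
    return None


def detect_outliers(
    table: RetentionTable,
    strt: StandardRetention | None = None,
    r_min: float = 0.99,
    resid_max: float = 1.5,
    compound_fraction: float = 0.25,
) -> ExclusionReport:
    """Screen a panel for nonlinear columns and deviating compounds.

    Compounds are screened first: a compound whose residual exceeds
    ``resid_max`` on more than ``compound_fraction`` of the columns deviates
    from the panel's shared linear behaviour and is excluded (otherwise every
    column it sits on would be flagged instead).  Columns are then refitted on
    the retained compounds and excluded when their correlation falls below
    ``r_min`` or any residual exceeds ``resid_max``.  The final St_R is
    recomputed from what remains.

    The compound screen works per column through trimmed leave-one-out fits
    (see :func:`_column_outlier_candidate`): raw residuals against a mean
    consensus cannot see a minority-offset compound (the offset drags its own
    St_R along and, at high leverage, hides in the fit), whereas the clean
    trimmed line recovers the full deviation.
    """
    complete = table.complete_columns()
    if not complete:
        raise ValueError("no complete columns to screen")
    if strt is None:
        strt = compute_strt(table, complete)

    names = [c for c in table.compounds if c in strt.compounds]
    Y = table.times.loc[names, complete].to_numpy(dtype=float)
    xs = _robust_consensus(strt.values[names].to_numpy(dtype=float), Y)

    votes = pd.Series(0, index=pd.Index(names))
    for j, col in enumerate(complete):
        i = _column_outlier_candidate(xs, Y[:, j], resid_max)
        if i is not None:
            votes.iloc[i] += 1
    frac_bad = votes / len(complete)
    excluded_compounds = {
        str(comp): (
            f"deviates > {resid_max} min from the column's trimmed fit on "
            f"{frac_bad[comp]:.0%} of columns (> {compound_fraction:.0%})"
        )
        for comp in frac_bad.index[frac_bad > compound_fraction]
    }
    retained_compounds = [c for c in table.compounds if c not in excluded_compounds]
    if len(retained_compounds) < 2:
        raise ValueError("fewer than two compounds retained; cannot screen columns")

    # column screen on the retained compounds, still against the robust axis;
    # a calibration map must have positive slope, so r is checked signed
    keep = [names.index(c) for c in retained_compounds if c in names]
    x2, Y2 = xs[keep], Y[keep, :]
    excluded_columns: dict[str, str] = {}
    for j, col in enumerate(complete):
        line = fit_least_squares(x2, Y2[:, j])
        resid = np.abs(Y2[:, j] - (line.slope * x2 + line.intercept))
        if line.r is not None and line.r < r_min:
            excluded_columns[col] = f"correlation {line.r:.4f} < {r_min}"
        elif float(resid.max()) > resid_max:
            excluded_columns[col] = (
                f"max residual {float(resid.max()):.3f} min > {resid_max} min"
            )
    retained_columns = [c for c in complete if c not in excluded_columns]
    if not retained_columns:
        raise ValueError("every column was excluded; panel unusable")

    sub = table.subset(compounds=retained_compounds)
    final = compute_strt(sub, retained_columns)
    fits = {c: fit_column_vs_strt(sub, final, c) for c in sub.complete_columns()}
    return ExclusionReport(
        excluded_columns=excluded_columns,
        excluded_compounds=excluded_compounds,
        retained_columns=tuple(retained_columns),
        retained_compounds=tuple(retained_compounds),
        final_strt=final,
        fits=fits,
    )


def _pair_mean_delta(
    table: RetentionTable, strt: StandardRetention, a: str, b: str, others: Sequence[str]
) -> float:
    """Mean two-point prediction deviation of a candidate pair over the panel."""
    deltas = []
    for col in table.complete_columns():
        t = table.times[col]
        line = fit_two_point((strt[a], strt[b]), (t[a], t[b]))
        for comp in others:
            deltas.append(abs(t[comp] - line(strt[comp])))
    return float(np.mean(deltas))


def select_reference_pair(
    table: RetentionTable,
    strt: StandardRetention | None = None,
    candidates: Iterable[str] | None = None,
    coverage_min: float = 0.8,
    excluded: Iterable[str] = (),
) -> tuple:
    """Choose the two reference compounds for a panel.

    Three steps: (1) keep candidate pairs whose St_R coverage is at least
    ``coverage_min`` (high coverage puts the references near both ends of the
    retention span); (2) drop pairs containing excluded / high-deviation
    compounds; (3) among the survivors, return the pair whose two-point
    prediction deviation, averaged over every panel column and every
    non-reference compound, is smallest.

    Returns ``(ReferencePair, ranking)`` where ``ranking`` is a DataFrame of
    every scored pair (coverage, eligibility, mean deviation) sorted best
    first.
    """
    if strt is None:
        strt = compute_strt(table, table.complete_columns())
    excluded = set(excluded)
    cands = [c for c in (candidates if candidates is not None else strt.compounds)]
    if len([c for c in cands if c not in excluded]) < 2:
        raise ValueError("need at least two candidate compounds after exclusion")

    rows = []
    for a, b in combinations(cands, 2):
        if strt[a] > strt[b]:
            a, b = b, a
        cov = coverage_of_tr(strt, a, b)
        eligible = cov >= coverage_min and not ({a, b} & excluded) and strt[a] != strt[b]
        others = [c for c in strt.compounds if c not in (a, b)]
        if strt[a] == strt[b]:
            mean_d = float("nan")  # degenerate pair cannot predict at all
        elif others:
            mean_d = _pair_mean_delta(table, strt, a, b, others)
        else:
            mean_d = 0.0
        rows.append(
            {"first": a, "second": b, "coverage": cov, "eligible": eligible, "mean_dtr": mean_d}
        )
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["eligible", "mean_dtr"], ascending=[False, True])
        .reset_index(drop=True)
    )
    top = ranking[ranking.eligible]
    if top.empty:
        best_cov = ranking.coverage.max()
        raise ValueError(
            f"no candidate pair reaches coverage {coverage_min}; best available "
            f"coverage is {best_cov:.3f} — consider lowering coverage_min"
        )
    best = top.iloc[0]
    return make_reference_pair(strt, best["first"], best["second"]), ranking


def _multi_fit_deltas(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-cell |OLS residual| of each column of Y regressed on x (vectorised)."""
    dx = x - x.mean()
    dY = Y - Y.mean(axis=0)
    sxx = float(dx @ dx)
    slopes = dx @ dY / sxx
    fitted = np.outer(dx, slopes) + Y.mean(axis=0)
    return np.abs(Y - fitted)


def subsample_study(
    table: RetentionTable,
    k_values: Sequence[int] = (1, 5, 10, 15, 20, 25, 30),
    n_draws: Sequence[int] | int = (30, 100, 100, 100, 100, 100, 1),
    seed: int = 0,
) -> SubsampleSummary:
    """How many columns does a stable St_R consensus need?

    For each panel size ``k``, distinct random column subsets are drawn
    without replacement; the consensus is computed on the subset, every
    column of the full panel is refitted against that consensus by ordinary
    least squares, and the mean absolute deviation of the fit is recorded.
    The per-k mean ± sd over draws shows how the prediction error shrinks
    with consensus size (the curve typically flattens by k ≈ 5).

    Draw counts follow the declared schedule; duplicate subsets are rejected,
    so draws are capped at C(N, k).  Deterministic for a given ``seed``.
    """
    cols = table.complete_columns()
    N = len(cols)
    if isinstance(n_draws, int):
        n_draws = [n_draws] * len(k_values)
    if len(n_draws) != len(k_values):
        raise ValueError("n_draws must be a scalar or parallel k_values")
    rng = np.random.default_rng(seed)
    Y = table.times[cols].to_numpy(dtype=float)  # K x N

    rows = []
    for k, wanted in zip(k_values, n_draws):
        if not 1 <= k <= N:
            raise ValueError(f"k={k} outside 1..{N}")
        limit = comb(N, k)
        target = min(int(wanted), limit)
        seen: set[frozenset] = set()
        per_draw = []
        while len(seen) < target:
            idx = frozenset(rng.choice(N, size=k, replace=False).tolist())
            if idx in seen:
                continue
            seen.add(idx)
            strt_k = Y[:, sorted(idx)].mean(axis=1)
            per_draw.append(float(_multi_fit_deltas(strt_k, Y).mean()))
        arr = np.asarray(per_draw)
        rows.append(
            {
                "k": k,
                "n_draws": target,
                "mean_dtr": float(arr.mean()),
                "sd_dtr": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows).set_index("k")
    return SubsampleSummary(table=out, seed=int(seed))
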