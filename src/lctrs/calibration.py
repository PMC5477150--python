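"""The two-reference calibration pipeline: predict, match, validate.

The pipeline runs in three stages on one target column:

1. **Two-point prediction** — the two reference substances are injected on
   the target column; the line through (St_R, t_mea) of the two references
   maps every analyte's St_R to a predicted time.
2. **Window matching** — each analyte is assigned the observed sample peak
   closest to its prediction within ±t_R_window.  Predictions closer together
   than ``series_gap`` that share a candidate peak form a *series* and are
   matched in elution order instead (order-preserving assignment), which
   resolves the swaps least-deviation matching is prone to for near peaks.
3. **Multi-point validation** — the matched (St_R, t_mea) points of the
   references *and* analytes are refitted by ordinary least squares; the
   refined predictions' deviations must all fall within t_R_limit for the
   prediction to count as a success.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    CalibrationLine,
    MatchConfig,
    PeakList,
    ReferencePair,
    RetentionTable,
    StandardRetention,
    compute_strt,
    delta_tr,
)

__all__ = [
    "PredictionSet",
    "AnalyteMatch",
    "MatchResult",
    "fit_two_point",
    "fit_least_squares",
    "predict",
    "match_peaks",
    "sequential_match",
    "validate_multipoint",
    "run_lctrs",
]

_UNASSIGNED_PENALTY = 1.0e9  # matching maximises assignments before minimising deviation


@dataclass(frozen=True)
class PredictionSet:
    """Predicted retention times (minutes) per analyte, with the line used."""

    predictions: Mapping[str, float]
    line: CalibrationLine
    stage: str  # "two_point" | "multi_point"

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.predictions.items() if not math.isfinite(v)}
        if bad:
            raise ValueError(f"non-finite predictions: {bad}")

    def __getitem__(self, analyte: str) -> float:
        return float(self.predictions[analyte])


@dataclass(frozen=True)
class AnalyteMatch:
    """One analyte's assignment: predicted time, observed peak (if any), Δt_R."""

    analyte: str
    predicted: float
    peak: float | None = None
    peak_index: int | None = None
    delta: float | None = None
    within_window: bool = False
    within_limit: bool = False
    in_series: bool = False


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one matching/validation stage on a target column.

    ``success`` at the matching stage means every analyte received a peak; at
    the validation stage it additionally requires every deviation to fall
    within its t_R_limit.  ``previous`` retains the earlier stage for
    reporting, so a validated result still exposes the two-point assignment.
    """

    matches: tuple
    line: CalibrationLine
    stage: str
    success: bool
    previous: "MatchResult | None" = None

    def match_for(self, analyte: str) -> AnalyteMatch:
        for m in self.matches:
            if m.analyte == analyte:
                return m
        raise KeyError(analyte)

    @property
    def deltas(self) -> dict:
        return {m.analyte: m.delta for m in self.matches}

    @property
    def assigned(self) -> dict:
        return {m.analyte: m.peak for m in self.matches if m.peak is not None}


def fit_two_point(
    ref_strt: Sequence[float], ref_tmea: Sequence[float]
) -> CalibrationLine:
    """Unique line through the two reference points (St_R, t_mea).

    ``ref_strt`` are the two references' standard retention times and
    ``ref_tmea`` their measured times on the target column, in the same order.
    """
    (s1, s2), (t1, t2) = ref_strt, ref_tmea
    if s1 == s2:
        raise ValueError("degenerate reference pair: identical St_R values")
    slope = (t2 - t1) / (s2 - s1)
    intercept = t1 - slope * s1
    return CalibrationLine(slope=slope, intercept=intercept, r=None, method="two_point")


def fit_least_squares(x: Sequence[float], y: Sequence[float]) -> CalibrationLine:
    """Ordinary least-squares line of measured times on St_R (vertical residuals)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise ValueError("least squares needs >= 2 distinct abscissae")
    if len(x) == 2:
        line = fit_two_point(x, y)
        r = 1.0 if line.slope >= 0 else -1.0  # interpolation is exact either way
        return CalibrationLine(line.slope, line.intercept, r=r, method="least_squares")
    res = stats.linregress(x, y)
    r = float(np.clip(res.rvalue, -1.0, 1.0))
    return CalibrationLine(slope=float(res.slope), intercept=float(res.intercept), r=r, method="least_squares")


def predict(
    line: CalibrationLine, strt_values: Mapping[str, float], stage: str | None = None
) -> PredictionSet:
    """Map analyte St_R values through the calibration line."""
    preds = {name: line(v) for name, v in strt_values.items()}
    return PredictionSet(predictions=preds, line=line, stage=stage or line.method)


def sequential_match(
    series_preds: Sequence[float],
    series_peaks: Sequence[float],
    allowed: Sequence[Sequence[int]] | None = None,
) -> list:
    """Order-preserving assignment of a prediction series to candidate peaks.

    Predictions (sorted ascending) are matched one-to-one, in order, to
    candidate peaks (sorted ascending): the earlier prediction takes the
    earlier peak.  With more peaks than predictions, the order-preserving
    assignment maximising the number of assignments and, among those,
    minimising the summed deviation is chosen.  ``allowed`` optionally
    restricts which peak indices each prediction may take (its window);
    with fewer usable peaks than predictions the surplus predictions are
    left unassigned (``None``).

    Returns a list of peak indices (into ``series_peaks``) or ``None``,
    parallel to ``series_preds``.
    """
    preds = [float(p) for p in series_preds]
    peaks = [float(q) for q in series_peaks]
    if any(b < a for a, b in zip(preds, preds[1:])):
        raise ValueError("series predictions must be sorted ascending")
    if any(b < a for a, b in zip(peaks, peaks[1:])):
        raise ValueError("series peaks must be sorted ascending")
    m, n = len(preds), len(peaks)
    if allowed is None:
        allowed = [range(n)] * m
    allowed = [set(a) for a in allowed]

    # DP over (prediction i, peak j): assign i->j, skip peak j, or leave i
    # unassigned.  Unassignment carries a large penalty so the assignment
    # count is maximised first, deviation minimised second.
    INF = float("inf")
    cost = [[INF] * (n + 1) for _ in range(m + 1)]
    choice = [[None] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        cost[m][j] = 0.0
    for i in range(m - 1, -1, -1):
        cost[i][n] = cost[i + 1][n] + _UNASSIGNED_PENALTY
        choice[i][n] = "drop"
        for j in range(n - 1, -1, -1):
            # tie order: take the earlier peak, else skip it, else drop the
            # prediction -- deterministic and order-respecting
            options = []
            if j in allowed[i]:
                options.append((abs(preds[i] - peaks[j]) + cost[i + 1][j + 1], 0, "take"))
            options.append((cost[i][j + 1], 1, "skip"))
            options.append((cost[i + 1][j] + _UNASSIGNED_PENALTY, 2, "drop"))
            best, _, act = min(options)
            cost[i][j], choice[i][j] = best, act

    out: list = [None] * m
    i = j = 0
    while i < m and j <= n:
        act = choice[i][j] if j < n else "drop"
        if act == "take":
            out[i] = j
            i, j = i + 1, j + 1
        elif act == "skip":
            j += 1
        else:
            i += 1
    return out


def _window_candidates(
    preds: PredictionSet, peaks: PeakList, cfg: MatchConfig
) -> dict:
    cand = {}
    for analyte, p in preds.predictions.items():
        w = cfg.window_for(analyte)
        cand[analyte] = [i for i, q in enumerate(peaks) if abs(q - p) <= w]
    return cand


def _series_components(
    order: list, preds: Mapping[str, float], cand: dict, gap: float
) -> list:
    """Connected components of analytes linked by closeness + a shared candidate."""
    parent = {a: a for a in order}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if abs(preds[a] - preds[b]) < gap and set(cand[a]) & set(cand[b]):
                parent[find(b)] = find(a)
    comps: dict[str, list] = {}
    for a in order:  # keep elution order within each component
        comps.setdefault(find(a), []).append(a)
    return list(comps.values())


def match_peaks(
    preds: PredictionSet, peaks: PeakList, cfg: MatchConfig | None = None
) -> MatchResult:
    """Assign observed peaks to predicted analyte times.

    Each analyte takes the least-deviation peak inside its window
    [t_pre − t_R_W, t_pre + t_R_W] (ties broken toward the earlier peak).
    Analytes whose predictions are closer than ``series_gap`` and whose
    windows share a candidate peak are treated as a series and matched in
    elution order (:func:`sequential_match`).  A peak may serve only one
    analyte; between non-series analytes the smaller deviation keeps it.
    Analytes with no usable peak are reported unassigned, not raised.
    """
    cfg = cfg or MatchConfig()
    order = sorted(preds.predictions, key=preds.predictions.__getitem__)
    cand = _window_candidates(preds, peaks, cfg)
    comps = _series_components(order, preds.predictions, cand, cfg.series_gap)

    assignment: dict[str, int | None] = {}
    in_series: dict[str, bool] = {}
    taken: set[int] = set()

    # series first: order-preserving assignment over the union of candidates
    for comp in comps:
        if len(comp) < 2:
            continue
        pool = sorted(set().union(*(cand[a] for a in comp)))
        allowed = [[pool.index(i) for i in cand[a] if i in pool] for a in comp]
        rel = sequential_match(
            [preds[a] for a in comp], [peaks.times[i] for i in pool], allowed
        )
        for a, r in zip(comp, rel):
            assignment[a] = pool[r] if r is not None else None
            in_series[a] = True
            if r is not None:
                taken.add(pool[r])

    # remaining analytes: least deviation, earlier peak on ties, one peak each
    solo = [a for comp in comps if len(comp) == 1 for a in comp]
    claims: dict[int, tuple[float, str]] = {}
    for a in solo:
        in_series[a] = False
        usable = [i for i in cand[a] if i not in taken]
        if not usable:
            assignment[a] = None
            continue
        deltas = [(abs(peaks.times[i] - preds[a]), i) for i in usable]
        d, i = min(deltas)
        prev = claims.get(i)
        if prev is None or d < prev[0]:
            if prev is not None:
                assignment[prev[1]] = None  # loser relinquishes, stays unassigned
            claims[i] = (d, a)
            assignment[a] = i
        else:
            assignment[a] = None

    matches = []
    for a in order:
        p = preds[a]
        i = assignment.get(a)
        if i is None:
            matches.append(AnalyteMatch(analyte=a, predicted=p, in_series=in_series.get(a, False)))
        else:
            q = peaks.times[i]
            d = delta_tr(q, p)
            matches.append(
                AnalyteMatch(
                    analyte=a,
                    predicted=p,
                    peak=q,
                    peak_index=i,
                    delta=d,
                    within_window=d <= cfg.window_for(a) + 1e-12,
                    within_limit=d <= cfg.limit_for(a) + 1e-12,
                    in_series=in_series.get(a, False),
                )
            )
    success = all(m.peak is not None for m in matches)
    return MatchResult(matches=tuple(matches), line=preds.line, stage=preds.stage, success=success)


def validate_multipoint(
    matched: MatchResult,
    ref_strt: Sequence[float],
    ref_tmea: Sequence[float],
    strt: StandardRetention | Mapping[str, float],
    cfg: MatchConfig | None = None,
) -> MatchResult:
    """Refit on references + matched analytes and re-score the deviations.

    The ordinary least-squares line over the (St_R, t_mea) points of the two
    references and every assigned analyte yields refined predictions; the
    prediction succeeds iff every analyte was assigned and every refined
    deviation is within its t_R_limit.  The two-point peak assignment is kept
    fixed; only the deviations are recomputed.
    """
    cfg = cfg or MatchConfig()
    get = strt.__getitem__
    xs = list(ref_strt)
    ys = list(ref_tmea)
    for m in matched.matches:
        if m.peak is not None:
            xs.append(get(m.analyte))
            ys.append(m.peak)
    line = fit_least_squares(xs, ys)

    new = []
    ok = True
    for m in matched.matches:
        p = line(get(m.analyte))
        if m.peak is None:
            ok = False
            new.append(replace(m, predicted=p, delta=None, within_window=False, within_limit=False))
        else:
            d = delta_tr(m.peak, p)
            within = d <= cfg.limit_for(m.analyte) + 1e-12
            ok = ok and within
            new.append(
                replace(
                    m,
                    predicted=p,
                    delta=d,
                    within_window=d <= cfg.window_for(m.analyte) + 1e-12,
                    within_limit=within,
                )
            )
    return MatchResult(
        matches=tuple(new), line=line, stage="multi_point", success=ok, previous=matched
    )


def run_lctrs(
    table_or_strt: RetentionTable | StandardRetention,
    pair: ReferencePair,
    ref_tmea: Sequence[float],
    peaks: PeakList,
    cfg: MatchConfig | None = None,
    analytes: Sequence[str] | None = None,
) -> MatchResult:
    """Full pipeline on one target column: fit → predict → match → validate.

    ``ref_tmea`` are the measured times of ``pair.first`` and ``pair.second``
    on the target column (from reference-substance injections), in that
    order.  ``analytes`` defaults to every other compound.  The returned
    result is the multi-point validation stage; the two-point stage is kept
    on its ``previous`` attribute.
    """
    cfg = cfg or MatchConfig()
    strt = (
        compute_strt(table_or_strt)
        if isinstance(table_or_strt, RetentionTable)
        else table_or_strt
    )
    if analytes is None:
        analytes = [c for c in strt.compounds if c not in (pair.first, pair.second)]
    ref_s = (strt[pair.first], strt[pair.second])
    line = fit_two_point(ref_s, ref_tmea)
    preds = predict(line, {a: strt[a] for a in analytes}, stage="two_point")
    matched = match_peaks(preds, peaks, cfg)
    return validate_multipoint(matched, ref_s, ref_tmea, strt, cfg)
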