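"""Relative-retention benchmark and panel-level method comparison.

Relative retention (RR) predicts an analyte's time on a new column as
``RR · t_ref`` from a single reference substance — geometrically, a
calibration line forced through the origin.  The adjusted variant anchors the
line at the column dead time ``t0`` instead (``t0 + RR_adj·(t_ref − t0)``).
Because real column-to-column maps have nonzero intercepts, both one-point
variants are systematically outperformed by the two-reference calibration;
this module quantifies that on a panel by sweeping every column as the
prediction target and tabulating the deviations of four methods: unadjusted
RR, adjusted RR, two-point prediction, and multi-point validation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import fit_least_squares, fit_two_point
from .core import (
    MatchConfig,
    ReferencePair,
    RetentionTable,
    StandardRetention,
    compute_strt,
)

__all__ = [
    "RRModel",
    "MethodReport",
    "rr_model_from_strt",
    "rr_predict",
    "evaluate_method",
    "compare_all",
]

METHODS = ("rr_unadjusted", "rr_adjusted", "lctrs_two_point", "lctrs_multi_point")


@dataclass(frozen=True)
class RRModel:
    """Relative-retention values anchored to one reference compound.

    ``rr`` maps compound → RR (dimensionless, 1 at the reference).  When
    ``adjusted`` is set the values are ratios of dead-time-corrected
    retention and ``t0`` (minutes, per use or per column) must be supplied to
    :func:`rr_predict`.
    """

    reference: str
    rr: pd.Series
    adjusted: bool = False

    def __post_init__(self) -> None:
        if self.reference not in self.rr.index:
            raise ValueError(f"reference {self.reference!r} missing from RR values")
        if not math.isclose(float(self.rr[self.reference]), 1.0, abs_tol=1e-9):
            raise ValueError("RR of the reference compound must be 1")
        if (self.rr <= 0).any():
            raise ValueError("RR values must be > 0")


def rr_model_from_strt(
    strt: StandardRetention, reference: str, t0: float = 0.0
) -> RRModel:
    """Derive RR values from the St_R consensus, optionally dead-time corrected.

    With ``t0 = 0`` this yields plain ratios ``St_R(i)/St_R(ref)``; a positive
    ``t0`` yields adjusted ratios on the dead-time-corrected scale.
    """
    if t0 < 0:
        raise ValueError("dead time must be >= 0")
    ref_v = strt[reference]
    if t0 >= ref_v:
        raise ValueError(f"dead time {t0} must be below the reference retention {ref_v}")
    vals = (strt.values - t0) / (ref_v - t0)
    return RRModel(reference=reference, rr=vals, adjusted=t0 > 0)


def rr_predict(
    model: RRModel,
    ref_tmea: float,
    analytes: Sequence[str] | None = None,
    t0: float | None = None,
) -> dict:
    """Predict analyte times from the reference's measured time on one column.

    Unadjusted: ``t_pre = RR · t_ref``.  Adjusted: ``t_pre = t0 + RR_adj ·
    (t_ref − t0)`` with the column's dead time ``t0``.
    """
    if ref_tmea <= 0:
        raise ValueError("measured reference time must be > 0")
    if model.adjusted:
        if t0 is None:
            raise ValueError("adjusted RR prediction requires the column dead time t0")
        if not 0 <= t0 < ref_tmea:
            raise ValueError("dead time must satisfy 0 <= t0 < reference time")
    else:
        t0 = 0.0
    names = list(analytes) if analytes is not None else [
        c for c in model.rr.index if c != model.reference
    ]
    return {a: t0 + float(model.rr[a]) * (ref_tmea - t0) for a in names}


@dataclass(frozen=True)
class MethodReport:
    """Panel-level deviation summary for one prediction method.

    ``delta_table`` holds |t_mea − t_pre| per (column, pending compound);
    ``positive_columns`` counts columns on which every pending compound's
    deviation is within its t_R_limit.  Chromatographic resolution, the other
    half of the full positive-column definition, needs raw chromatograms and
    is flagged as not evaluated.
    """

    method: str
    max_dtr: float
    mean_dtr: float
    positive_columns: int
    delta_table: pd.DataFrame  # columns = compounds, index = panel columns
    t_r_limit: float
    pending_compounds: tuple
    resolution_evaluated: bool = False

    def __post_init__(self) -> None:
        if self.max_dtr + 1e-12 < self.mean_dtr:
            raise ValueError("max deviation cannot be below the mean")


def evaluate_method(
    delta_table: pd.DataFrame, cfg: MatchConfig, method: str
) -> MethodReport:
    """Summarise a per-column × per-compound deviation table.

    ``delta_table`` is indexed by panel column with one column per pending
    compound.  A panel column is positive when every pending compound's
    deviation is within its (possibly overridden) t_R_limit.
    """
    if delta_table.empty:
        raise ValueError("empty deviation table")
    limits = pd.Series({c: cfg.limit_for(c) for c in delta_table.columns})
    ok = delta_table.le(limits + 1e-12, axis=1).all(axis=1)
    vals = delta_table.to_numpy(dtype=float)
    return MethodReport(
        method=method,
        max_dtr=float(np.nanmax(vals)),
        mean_dtr=float(np.nanmean(vals)),
        positive_columns=int(ok.sum()),
        delta_table=delta_table,
        t_r_limit=cfg.t_r_limit,
        pending_compounds=tuple(delta_table.columns),
    )


def compare_all(
    table: RetentionTable,
    rr_model: RRModel,
    pair: ReferencePair,
    strt: StandardRetention | None = None,
    cfg: MatchConfig | None = None,
    t0: float | Mapping[str, float] | None = None,
) -> dict:
    """Run the four prediction methods column-by-column over a panel.

    Every panel column in turn plays the target: reference measured times are
    read from the table, the remaining (pending) compounds are predicted and
    their deviations recorded.  Pending compounds are all non-reference
    compounds of each method (three for the single-reference RR variants, two
    for the two-reference calibration on the bundled Paridis panel).  The
    adjusted RR variant runs only when a dead time ``t0`` (scalar or mapping
    column → minutes) is supplied.

    Returns ``{"reports": {method: MethodReport}, "ranking": DataFrame}``
    with the ranking sorted by mean deviation.
    """
    cfg = cfg or MatchConfig()
    if strt is None:
        strt = compute_strt(table, table.complete_columns())
    cols = table.complete_columns()
    if not cols:
        raise ValueError("panel has no complete columns")

    rr_pending = [c for c in table.compounds if c != rr_model.reference]
    lc_pending = [c for c in table.compounds if c not in (pair.first, pair.second)]

    def t0_for(col: str) -> float | None:
        if t0 is None:
            return None
        return float(t0[col]) if isinstance(t0, Mapping) else float(t0)

    deltas: dict[str, dict] = {m: {} for m in METHODS}
    for col in cols:
        t = table.times[col]

        ref_t = float(t[rr_model.reference])
        preds = rr_predict(rr_model, ref_t, rr_pending)
        deltas["rr_unadjusted"][col] = {a: abs(t[a] - p) for a, p in preds.items()}

        tc = t0_for(col)
        if tc is not None:
            adj = rr_model_from_strt(strt, rr_model.reference, t0=tc)
            preds = rr_predict(adj, ref_t, rr_pending, t0=tc)
            deltas["rr_adjusted"][col] = {a: abs(t[a] - p) for a, p in preds.items()}

        ref_s = (strt[pair.first], strt[pair.second])
        ref_m = (float(t[pair.first]), float(t[pair.second]))
        two = fit_two_point(ref_s, ref_m)
        deltas["lctrs_two_point"][col] = {
            a: abs(t[a] - two(strt[a])) for a in lc_pending
        }

        xs = list(ref_s) + [strt[a] for a in lc_pending]
        ys = list(ref_m) + [float(t[a]) for a in lc_pending]
        multi = fit_least_squares(xs, ys)
        deltas["lctrs_multi_point"][col] = {
            a: abs(t[a] - multi(strt[a])) for a in lc_pending
        }

    reports = {}
    for method in METHODS:
        if not deltas[method]:
            continue  # adjusted RR without a dead time
        dt = pd.DataFrame.from_dict(deltas[method], orient="index")
        reports[method] = evaluate_method(dt, cfg, method)

    ranking = (
        pd.DataFrame(
            {
                "method": list(reports),
                "max_dtr": [r.max_dtr for r in reports.values()],
                "mean_dtr": [r.mean_dtr for r in reports.values()],
                "positive_columns": [r.positive_columns for r in reports.values()],
            }
        )
        .sort_values("mean_dtr")
        .reset_index(drop=True)
    )
    return {"reports": reports, "ranking": ranking}
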