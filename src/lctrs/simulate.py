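"""Synthetic retention panels with known ground truth.

The generator emulates the structure the calibration method assumes: each
column j maps the true consensus axis affinely, ``t[i, j] = a_j·St_i + b_j +
ε``, with per-column slopes and intercepts drawn around identity and i.i.d.
Gaussian measurement noise.  Defaults mirror the scale of the bundled
four-saponin panel: 4 compounds spanning ~20–33 min on 30 columns, slope sd
0.07, intercept sd 1 min, noise sd 0.05 min.  Two outlier mechanisms seen in
real panels can be injected for detection studies: whole-column shuffles
(destroyed linearity, e.g. a mis-labelled run) and per-compound offsets on a
fraction of columns (an analyte whose retention behaviour departs from the
panel's shared linearity on part of the hardware).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import RetentionTable

__all__ = ["PanelSpec", "generate_panel"]

_DEFAULT_COMPOUNDS: Mapping[str, float] = {
    "compound A": 19.8,
    "compound B": 22.1,
    "compound C": 30.3,
    "compound D": 33.0,
}


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of one synthetic panel; the seed is mandatory.

    ``compounds`` maps compound name → true St_R (minutes).  ``shuffle_columns``
    columns get their compound times randomly permuted (non-identity);
    ``offset_compound`` (if set) gains ``offset_magnitude`` minutes on a
    random ``offset_fraction`` of the columns.
    """

    seed: int
    n_columns: int = 30
    compounds: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_COMPOUNDS))
    slope_mean: float = 1.0
    slope_sd: float = 0.07
    intercept_mean: float = 0.0
    intercept_sd: float = 1.0
    noise_sd: float = 0.05
    shuffle_columns: int = 0
    offset_compound: str | None = None
    offset_magnitude: float = 3.0
    offset_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")
        if min(self.slope_sd, self.intercept_sd, self.noise_sd) < 0:
            raise ValueError("spread parameters must be >= 0")
        if len(self.compounds) < 2:
            raise ValueError("need at least two compounds")
        if any(v <= 0 for v in self.compounds.values()):
            raise ValueError("true St_R values must be > 0")
        if self.shuffle_columns < 0 or self.shuffle_columns > self.n_columns:
            raise ValueError("shuffle_columns outside 0..n_columns")
        if self.offset_compound is not None and self.offset_compound not in self.compounds:
            raise ValueError(f"unknown offset compound {self.offset_compound!r}")
        if not 0 <= self.offset_fraction <= 1:
            raise ValueError("offset_fraction must lie in [0, 1]")


def generate_panel(spec: PanelSpec) -> tuple:
    """Draw one panel; returns ``(RetentionTable, truth)``.

    ``truth`` records everything a recovery test needs: per-column true
    slopes/intercepts (pd.Series), the true St_R values, which columns were
    shuffled and which (compound, column) cells were offset.  Deterministic
    for a given spec (all randomness flows through one generator seeded by
    ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.compounds)
    st_true = np.array([spec.compounds[c] for c in names], dtype=float)
    cols = [f"syn{j + 1}" for j in range(spec.n_columns)]

    slopes = rng.normal(spec.slope_mean, spec.slope_sd, spec.n_columns)
    intercepts = rng.normal(spec.intercept_mean, spec.intercept_sd, spec.n_columns)
    noise = rng.normal(0.0, spec.noise_sd, (len(names), spec.n_columns))
    t = np.outer(st_true, slopes) + intercepts[None, :] + noise

    shuffled = sorted(rng.choice(spec.n_columns, size=spec.shuffle_columns, replace=False).tolist())
    for j in shuffled:
        perm = rng.permutation(len(names))
        while np.all(perm == np.arange(len(names))):  # force a real shuffle
            perm = rng.permutation(len(names))
        t[:, j] = t[perm, j]

    offset_cells: list[tuple] = []
    if spec.offset_compound is not None and spec.offset_fraction > 0:
        k = int(round(spec.offset_fraction * spec.n_columns))
        hit = sorted(rng.choice(spec.n_columns, size=k, replace=False).tolist())
        i = names.index(spec.offset_compound)
        t[i, hit] += spec.offset_magnitude
        offset_cells = [(spec.offset_compound, cols[j]) for j in hit]

    times = pd.DataFrame(t, index=pd.Index(names, name="compound"), columns=cols)
    truth = {
        "slopes": pd.Series(slopes, index=cols),
        "intercepts": pd.Series(intercepts, index=cols),
        "st_r_true": pd.Series(st_true, index=names),
        "shuffled_columns": [cols[j] for j in shuffled],
        "offset_cells": offset_cells,
    }
    return RetentionTable(times), truth
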