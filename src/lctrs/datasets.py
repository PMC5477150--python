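"""Bundled reference data: the Paridis saponin panel and distributed RR/St_R lists.

The Paridis Rhizome panel is the method's worked dataset: retention times of
four steroidal saponins (Chonglou saponins VII, VI, II, I) measured on 30
C_18 columns from 13 manufacturers under one gradient program, with
injection-replicate standard deviations.  Reference-value lists (consensus
St_R and relative retention, with the designated reference compounds) are
bundled for both Paridis and Psoraleae Fructus; the Psoraleae per-column
retention matrix was never distributed, so only its reference lists ship.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .comparison import RRModel
from .core import RetentionTable, StandardRetention

__all__ = [
    "paridis_panel",
    "paridis_column_info",
    "paridis_reference_values",
    "psoraleae_reference_values",
    "paridis_rr_model",
    "paridis_consensus",
    "psoraleae_consensus",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("lctrs.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def paridis_panel() -> RetentionTable:
    """The 4-saponin × 30-column Paridis retention table (minutes)."""
    df = _read("paridis_retention.csv").set_index("compound")
    time_cols = [c for c in df.columns if not c.endswith("_sd")]
    sd = df[[c + "_sd" for c in time_cols]]
    sd.columns = time_cols
    return RetentionTable(df[time_cols], sd)


def paridis_column_info() -> pd.DataFrame:
    """Brand and geometry of the 30 panel columns."""
    return _read("paridis_columns.csv").set_index("column")


def paridis_reference_values() -> pd.DataFrame:
    """Distributed reference list for Paridis: St_R, RR and reference flags.

    Note: the distributed consensus for Chonglou saponin VI (22.156 min)
    differs from the bundled panel's own column average (22.110 min); the
    panel average is authoritative in this package and matches the worked
    two-reference example.
    """
    return _read("paridis_references.csv").set_index("compound")


def psoraleae_reference_values() -> pd.DataFrame:
    """Distributed reference list for Psoraleae (11 peaks, 23-column consensus)."""
    return _read("psoraleae_references.csv").set_index("compound")


def paridis_rr_model() -> RRModel:
    """Distributed relative-retention values (reference: Chonglou saponin II)."""
    ref = paridis_reference_values()
    reference = ref.index[ref.rr_reference][0]
    return RRModel(reference=reference, rr=ref["rr"].astype(float))


def _consensus(ref: pd.DataFrame, n: int) -> StandardRetention:
    return StandardRetention(
        values=ref["st_r_min"].astype(float),
        columns_used=frozenset(),  # distributed list; source columns not itemised
        n=n,
    )


def paridis_consensus() -> StandardRetention:
    """Distributed Paridis St_R list (30-column consensus as printed)."""
    return _consensus(paridis_reference_values(), 30)


def psoraleae_consensus() -> StandardRetention:
    """Distributed Psoraleae St_R list (23-column consensus as printed)."""
    return _consensus(psoraleae_reference_values(), 23)
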