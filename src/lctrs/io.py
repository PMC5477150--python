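"""CSV/JSON readers and writers for retention tables, peak lists and reports.

Retention-table CSV dialect: comma-separated, UTF-8, period decimal
separator, mandatory header row; first column ``compound``, one column per
chromatographic column identifier, cells in minutes; optional parallel
``<column>_sd`` columns carry injection-replicate standard deviations.
Peak-list CSV: one ``retention_time_min`` value per row.
"""
from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import PeakList, RetentionTable, StandardRetention

__all__ = [
    "read_retention_table",
    "write_retention_table",
    "read_peak_list",
    "write_peak_list",
    "write_standard_retention",
    "read_standard_retention",
    "to_jsonable",
    "write_report",
]


def read_retention_table(path) -> RetentionTable:
    """Read a retention table CSV, validating shape and values.

    Rejects duplicate compound/column identifiers, non-numeric cells and
    non-positive retention times, naming the offending cell.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        try:
            header = next(csv.reader(fh))
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
    body = [h for h in header[1:] if not h.endswith("_sd")]
    dupes = {h for h in body if body.count(h) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate column identifiers: {sorted(dupes)}")

    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    sd_cols = [c for c in df.columns if c.endswith("_sd")]
    time_cols = [c for c in df.columns if not c.endswith("_sd")]
    times = df[time_cols]
    for comp, row in times.iterrows():
        for col, v in row.items():
            x = pd.to_numeric(v, errors="coerce")
            if pd.isna(x) and not (isinstance(v, float) and pd.isna(v)):
                raise ValueError(f"{path}: non-numeric cell ({comp!r}, {col!r}) = {v!r}")
            if pd.notna(x) and x <= 0:
                raise ValueError(f"{path}: non-positive cell ({comp!r}, {col!r}) = {v!r}")
    times = times.apply(pd.to_numeric)
    sd = None
    if sd_cols:
        sd = df[sd_cols].apply(pd.to_numeric)
        sd.columns = [c[: -len("_sd")] for c in sd_cols]
    return RetentionTable(times, sd)


def write_retention_table(table: RetentionTable, path) -> None:
    out = table.times.copy()
    if table.sd is not None:
        for c in table.times.columns:
            out[f"{c}_sd"] = table.sd[c]
    out.index.name = "compound"
    out.to_csv(path)


def read_peak_list(path) -> PeakList:
    """Read a peak list CSV (``retention_time_min`` per row, sorted ascending)."""
    df = pd.read_csv(path)
    col = "retention_time_min" if "retention_time_min" in df.columns else df.columns[0]
    times = [float(v) for v in df[col]]
    labels = tuple(df["label"]) if "label" in df.columns else None
    return PeakList(times=tuple(times), labels=labels)


def write_peak_list(peaks: PeakList, path) -> None:
    df = pd.DataFrame({"retention_time_min": list(peaks.times)})
    if peaks.labels is not None:
        df["label"] = list(peaks.labels)
    df.to_csv(path, index=False)


def write_standard_retention(strt: StandardRetention, path) -> None:
    """Two-column CSV (compound, st_r_min) plus a JSON sidecar of columns used."""
    path = Path(path)
    strt.values.rename("st_r_min").to_csv(path, index_label="compound")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps({"columns_used": sorted(strt.columns_used), "n": strt.n}, indent=2)
    )


def read_standard_retention(path) -> StandardRetention:
    path = Path(path)
    s = pd.read_csv(path, index_col=0)["st_r_min"]
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text())
    return StandardRetention(
        values=s, columns_used=frozenset(meta["columns_used"]), n=int(meta["n"])
    )


def to_jsonable(obj: Any) -> Any:
    """Recursively convert package objects to JSON-serialisable structures.

    Floats are kept at full precision (Python ``repr`` round-trips bit-exact);
    dataclasses become dicts tagged with their type name.
    """
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, (float, np.floating)):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, pd.Series):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {str(c): to_jsonable(obj[c]) for c in obj.columns}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {"_type": type(obj).__name__}
        for f in dataclasses.fields(obj):
            d[f.name] = to_jsonable(getattr(obj, f.name))
        return d
    if isinstance(obj, RetentionTable):
        return {
            "_type": "RetentionTable",
            "times": to_jsonable(obj.times),
            "sd": to_jsonable(obj.sd) if obj.sd is not None else None,
        }
    if isinstance(obj, (frozenset, set)):
        return sorted(to_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    raise TypeError(f"cannot serialise {type(obj).__name__}")


def _method_reports_csv(reports, path) -> None:
    rows = [
        {
            "method": r.method,
            "max_dtr": r.max_dtr,
            "mean_dtr": r.mean_dtr,
            "positive_columns": r.positive_columns,
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _render_text(data: Any, indent: int = 0) -> str:
    pad = "  " * indent
    if isinstance(data, dict):
        lines = []
        for k, v in data.items():
            if isinstance(v, (dict, list)):
                lines.append(f"{pad}{k}:")
                lines.append(_render_text(v, indent + 1))
            else:
                lines.append(f"{pad}{k}: {v}")
        return "\n".join(lines)
    if isinstance(data, list):
        return "\n".join(_render_text(v, indent) for v in data)
    return f"{pad}{data}"


def write_report(results: Any, path, format: str = "json") -> None:
    """Write a results object as round-trippable JSON, CSV or readable text.

    JSON keeps every numeric field at full precision; reading the file back
    reproduces the numbers bit-exactly.  CSV is supported for lists of
    :class:`~lctrs.comparison.MethodReport`; text is a human-readable
    rendering of the JSON structure.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(to_jsonable(results), indent=2) + "\n")
    elif format == "csv":
        from .comparison import MethodReport

        if isinstance(results, (list, tuple)) and all(
            isinstance(r, MethodReport) for r in results
        ):
            _method_reports_csv(results, path)
        else:
            raise ValueError("csv format supports a list of MethodReport objects")
    elif format == "text":
        path.write_text(_render_text(to_jsonable(results)) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
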