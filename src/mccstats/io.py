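"""File readers and report writers.

Formats (all plain text, CSV/TSV/JSON):

* single count files — header ``tp,fp,fn,tn``, one data row;
* paired count files — columns ``i,j,k,count`` covering all 8 cells of
  (pred1, pred2, actual) exactly once;
* label files — columns ``actual,predicted`` (single) or
  ``actual,pred1,pred2`` (paired), values 0/1;
* reports — JSON or TSV with stable field order, floats at 6
  significant digits, NA rendered as the literal string ``NA`` with a
  reason field.
"""

from __future__ import annotations

import dataclasses
import json
import math
import sys
from typing import Optional, Union

import numpy as np
import pandas as pd

from .confusion import ConfusionCounts, PairedCounts
from .errors import InputError

__all__ = ["read_counts", "read_labels", "write_report", "format_value"]


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except FileNotFoundError:
        raise InputError(f"file not found: {path}")
    except Exception as exc:  # malformed CSV
        raise InputError(f"cannot parse {path}: {exc}")


def read_counts(path) -> Union[ConfusionCounts, PairedCounts]:
    """Read a 2x2 or paired count file, dispatching on the header."""
    df = _read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if cols == ["tp", "fp", "fn", "tn"]:
        if len(df) != 1:
            raise InputError(f"{path}: expected exactly one data row, found {len(df)}")
        row = df.iloc[0]
        _require_integers(row, path, line=2)
        return ConfusionCounts(int(row.tp), int(row.fp), int(row.fn), int(row.tn))
    if cols == ["i", "j", "k", "count"]:
        if len(df) != 8:
            raise InputError(
                f"{path}: paired count file must have 8 rows (one per cell), found {len(df)}"
                + (": missing cell" if len(df) < 8 else "")
            )
        cells = np.full((2, 2, 2), -1, dtype=int)
        for pos, row in df.iterrows():
            line = pos + 2  # header is line 1
            _require_integers(row, path, line)
            i, j, k, cnt = int(row.i), int(row.j), int(row["k"]), int(row["count"])
            if not all(v in (0, 1) for v in (i, j, k)):
                raise InputError(f"{path} line {line}: cell indices must be 0/1")
            if cnt < 0:
                raise InputError(f"{path} line {line}: negative count {cnt}")
            if cells[i, j, k] >= 0:
                raise InputError(f"{path} line {line}: duplicate cell ({i},{j},{k})")
            cells[i, j, k] = cnt
        return PairedCounts.from_array(cells)
    raise InputError(
        f"{path}: malformed header {list(df.columns)!r}; expected tp,fp,fn,tn or i,j,k,count"
    )


def _require_integers(row, path, line: int) -> None:
    for name, v in row.items():
        if pd.isna(v):
            raise InputError(f"{path} line {line}: missing value in column {name!r}")
        if float(v) != int(v):
            raise InputError(f"{path} line {line}: non-integer value {v!r} in column {name!r}")


def read_labels(path, paired: bool = False):
    """Read binary label columns; returns (actual, predicted) vectors or
    (actual, pred1, pred2) in paired mode."""
    df = _read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    want = ["actual", "pred1", "pred2"] if paired else ["actual", "predicted"]
    for col in want:
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r} (have {list(df.columns)})")
    n_missing = int(df[want].isna().any(axis=1).sum())
    if n_missing:
        raise InputError(f"{path}: {n_missing} row(s) with missing values rejected")
    out = []
    for col in want:
        v = df[col].to_numpy()
        bad = ~np.isin(v, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise InputError(
                f"{path}: non-binary value {v[row]!r} in column {col!r} at row {row + 2}"
            )
        out.append(v.astype(int))
    return tuple(out)


def format_value(v) -> str:
    """Render a value for a report: 6 significant digits, NA for nan."""
    if v is None:
        return "NA"
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return f"{v:.6g}"
    return str(v)


def _as_record(result) -> dict:
    if dataclasses.is_dataclass(result):
        return dataclasses.asdict(result)
    if isinstance(result, dict):
        return dict(result)
    raise InputError(f"cannot serialize result of type {type(result).__name__}")


def write_report(results, format: str = "json", path: Optional[str] = None) -> str:
    """Serialize analysis results (dataclasses or dicts) to JSON or TSV.

    Returns the rendered text; writes it to ``path`` (or stdout when
    ``path`` is None).
    """
    if not isinstance(results, (list, tuple)):
        results = [results]
    records = [_as_record(r) for r in results]
    if format == "json":
        rendered = [
            {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in rec.items()}
            for rec in records
        ]
        text = json.dumps(rendered if len(rendered) > 1 else rendered[0], indent=2) + "\n"
    elif format == "tsv":
        keys = list(records[0].keys())
        lines = ["\t".join(keys)]
        for rec in records:
            lines.append("\t".join(format_value(rec.get(k)) for k in keys))
        text = "\n".join(lines) + "\n"
    else:
        raise InputError(f"unknown report format {format!r}")
    if path is None:
        sys.stdout.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
    return text
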