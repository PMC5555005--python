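"""Table readers and result writers."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset
from .selection import SelectionResult, _jsonable

__all__ = [
    "read_table",
    "write_result_json",
    "read_result_json",
    "write_records_csv",
]


def read_table(path, outcome: str) -> Dataset:
    """Read a CSV/TSV file with a header row into a :class:`Dataset`.

    The delimiter is sniffed from the extension (``.tsv``/``.txt`` ->
    tab, otherwise comma).  Rows containing any missing value are
    rejected with a count in the error message; non-numeric covariate
    cells and duplicate header names raise as well.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    # pandas silently renames duplicated header names; check the raw header
    with open(path) as fh:
        header = next(csv.reader(fh, delimiter=sep))
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate column names in {path}: {dupes}")
    df = pd.read_csv(path, sep=sep)
    if outcome not in df.columns:
        raise KeyError(
            f"outcome column {outcome!r} not found in {path} "
            f"(columns: {list(df.columns)[:10]}...)"
        )
    non_numeric = [
        c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)
    ]
    if non_numeric:
        raise ValueError(f"non-numeric columns in {path}: {non_numeric}")
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        raise ValueError(
            f"{n_missing} row(s) in {path} contain missing values; "
            "remove or impute them first"
        )
    return Dataset.from_dataframe(df, outcome=outcome)


def write_result_json(result, path) -> None:
    """Serialise a selection-type result (anything with ``to_dict``)."""
    path = Path(path)
    payload = result.to_dict() if hasattr(result, "to_dict") else _jsonable(result)
    try:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"could not write result to {path}: {exc}") from exc


def read_result_json(path) -> SelectionResult:
    with open(path) as fh:
        return SelectionResult.from_dict(json.load(fh))


def write_records_csv(records: pd.DataFrame, path) -> None:
    """Write a long-format benchmark table."""
    path = Path(path)
    try:
        records.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"could not write records to {path}: {exc}") from exc
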