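"""Readers and writers for every matrix and metadata artifact.

All matrices travel as TSV with explicit row and column ID headers (first
column = row ID), bins as BED (0-based half-open), configs as YAML and run
metadata as JSON.  Writing then reading reproduces integer matrices exactly
and floats to full precision (17 significant digits).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import BinSet

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_bins",
    "read_bins",
    "write_json",
    "read_json",
]


def write_matrix(
    path: str | Path,
    matrix: np.ndarray,
    row_ids: list[str],
    col_ids: list[str],
    index_name: str = "id",
) -> None:
    matrix = np.asarray(matrix)
    if matrix.shape != (len(row_ids), len(col_ids)):
        raise ValueError("matrix shape does not match row/column IDs")
    float_fmt = "%.17g" if np.issubdtype(matrix.dtype, np.floating) else "%d"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([index_name, *col_ids])
        for rid, row in zip(row_ids, matrix):
            w.writerow([rid, *(float_fmt % v for v in row)])


def read_matrix(
    path: str | Path, dtype=np.float64
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a TSV matrix; returns (values, row_ids, col_ids).

    Malformed input raises with the offending row or column named.
    """
    path = Path(path)
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ValueError(f"{path}: header must name at least one column")
        col_ids = header[1:]
        row_ids, rows = [], []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise ValueError(
                    f"{path}: line {lineno} has {len(rec)} fields, "
                    f"expected {len(header)} (ragged row)"
                )
            row_ids.append(rec[0])
            try:
                rows.append([dtype(v) for v in rec[1:]])
            except ValueError:
                bad = next(
                    c for c, v in zip(col_ids, rec[1:])
                    if not _is_number(v)
                )
                raise ValueError(
                    f"{path}: non-numeric value in row {rec[0]!r}, "
                    f"column {bad!r} (line {lineno})"
                ) from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=dtype), row_ids, col_ids


def _is_number(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def write_bins(path: str | Path, bins: BinSet) -> None:
    pd.DataFrame(
        {"chrom": bins.chroms, "start": bins.starts, "end": bins.ends}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_bins(path: str | Path) -> BinSet:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    return BinSet(
        chroms=df["chrom"].to_numpy(dtype=object),
        starts=df["start"].to_numpy(dtype=np.int64),
        ends=df["end"].to_numpy(dtype=np.int64),
    )


def write_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
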