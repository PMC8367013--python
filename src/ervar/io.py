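"""CSV handling for response matrices and prediction vectors.

Dialect: comma-separated, UTF-8, '.' decimal, optional '#' comment lines.
A header row and a leading stimulus-ID column are auto-detected (a row or
column is treated as labels when it fails float conversion).  Bodies must be
rectangular; ragged rows are rejected with the offending row named.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .core import Predictions, ResponseMatrix

__all__ = [
    "read_response_csv",
    "read_predictions_csv",
    "write_response_csv",
]


def _read_rows(path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            cells = [c.strip() for c in row]
            if any(cells):
                rows.append((lineno, cells))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return rows


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def _parse_table(path) -> np.ndarray:
    rows = _read_rows(path)
    width = len(rows[0][1])
    for lineno, cells in rows:
        if len(cells) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno} ({len(cells)} cells, expected "
                f"{width}); response matrices must be rectangular"
            )
    # A header row is only considered if the first row contains a non-numeric
    # cell; an ID column only if some row starts with a non-numeric cell.
    header_possible = any(not _is_float(c) for c in rows[0][1])
    idcol_possible = width > 1 and any(not _is_float(r[1][0]) for r in rows)
    layouts = [(False, False)]
    if idcol_possible:
        layouts.append((False, True))
    if header_possible:
        layouts.append((True, False))
        if idcol_possible:
            layouts.append((True, True))

    def all_numeric(skip_header: bool, id_col: bool) -> bool:
        body = rows[1:] if skip_header else rows
        return bool(body) and all(
            _is_float(c) for _, cells in body for c in cells[1 if id_col else 0:]
        )

    for skip_header, id_col in layouts:
        if all_numeric(skip_header, id_col):
            body = rows[1:] if skip_header else rows
            start = 1 if id_col else 0
            return np.array(
                [[float(c) for c in cells[start:]] for _, cells in body], dtype=float
            )

    body = rows[1:] if header_possible and len(rows) > 1 else rows
    start = 1 if idcol_possible else 0
    for lineno, cells in body:
        for j, cell in enumerate(cells[start:], start=start):
            if not _is_float(cell):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at line {lineno}, column {j + 1}"
                )
    raise ValueError(f"{path}: could not parse a numeric table")


def read_response_csv(path) -> ResponseMatrix:
    """Read an m x n response matrix (rows = stimuli, columns = repeats)."""
    return ResponseMatrix(_parse_table(path))


def read_predictions_csv(path, dof: int = 1) -> Predictions:
    """Read a length-m prediction vector (single column, or single row)."""
    arr = _parse_table(path)
    if 1 not in arr.shape and arr.ndim == 2:
        raise ValueError(
            f"{path}: predictions must be a single column or row, got shape {arr.shape}"
        )
    return Predictions(arr.ravel(), dof=dof)


def write_response_csv(path, Y, header: bool = False) -> None:
    """Write a response matrix in the package dialect (bit-exact round-trip)."""
    Y = Y.values if isinstance(Y, ResponseMatrix) else np.asarray(Y)
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow([f"rep{j}" for j in range(Y.shape[1])])
        for row in Y:
            writer.writerow([repr(float(v)) for v in row])
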