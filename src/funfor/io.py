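"""Delimited-text and JSON input/output, checksums, and run provenance.

Curve matrices and predictor tables travel as plain comma- or tab-separated
text (delimiter auto-detected); fitted objects serialize to JSON with full
float precision, so write-read round trips are lossless.
"""

from __future__ import annotations

import csv
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CurveMatrix, Grid, PredictorTable, rescale_grid
from .exceptions import InvalidInputError, ParseError
from .forest import FunForForest, PvimResult
from .fpca import FpcaModel


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") and "\t" in first_line else ","


def _parse_rows(path) -> list[list[str]]:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    return list(csv.reader(lines, delimiter=delim))


def read_curves(path, header: str | bool = "auto") -> CurveMatrix:
    """Read a curve matrix (one row per observation) from delimited text.

    An optional first row may hold the grid positions (strictly increasing;
    rescaled onto [0, 1]); otherwise a uniform grid is assumed.  With
    ``header='auto'`` the first row is taken as a grid header when it is
    strictly increasing while at least one data row is not.
    """
    rows = _parse_rows(path)
    width = len(rows[0])
    numeric = []
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ParseError(f"{path}: row {i + 1} has {len(row)} fields, expected {width}")
        vals = []
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell == "":
                raise ParseError(f"{path}: missing cell at row {i + 1}, column {j + 1}")
            try:
                vals.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 1}, column {j + 1}"
                ) from None
        numeric.append(vals)
    arr = np.asarray(numeric)
    increasing = [bool(np.all(np.diff(r) > 0)) for r in arr]
    if header == "auto":
        has_header = increasing[0] and len(arr) > 1 and not all(increasing[1:])
    else:
        has_header = bool(header)
    if has_header:
        grid = rescale_grid(arr[0])
        data = arr[1:]
    else:
        grid = Grid.uniform(arr.shape[1])
        data = arr
    if data.shape[0] == 0:
        raise ParseError(f"{path}: no data rows")
    return CurveMatrix(data, grid)


def write_curves(path, curves: CurveMatrix, delimiter: str = ",", grid_header: bool = True):
    with open(path, "w") as fh:
        if grid_header:
            fh.write(delimiter.join(repr(float(x)) for x in curves.grid.points) + "\n")
        for row in curves.values:
            fh.write(delimiter.join(repr(float(x)) for x in row) + "\n")


def read_predictors(path, type_overrides=None) -> PredictorTable:
    """Read a predictor table (header row of names) from delimited text."""
    rows = _parse_rows(path)
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one data row")
    names = [c.strip() for c in rows[0]]
    try:
        df = pd.DataFrame(
            [[float(c) for c in row] for row in rows[1:]], columns=names
        )
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric predictor value ({exc})") from None
    if any(len(row) != len(names) for row in rows[1:]):
        raise ParseError(f"{path}: ragged predictor rows")
    return PredictorTable.from_dataframe(df, type_overrides)


def write_predictors(path, table: PredictorTable, delimiter: str = ","):
    with open(path, "w") as fh:
        fh.write(delimiter.join(table.column_names) + "\n")
        for row in table.values:
            fh.write(delimiter.join(repr(float(x)) for x in row) + "\n")


def write_pvim(path, result: PvimResult):
    """Ranked two-column (name, score) tab-separated importance listing."""
    with open(path, "w") as fh:
        fh.write("predictor\tpvim\n")
        for j in result.ranking:
            fh.write(f"{result.column_names[j]}\t{result.scores[j]!r}\n")


def save_json(path, obj):
    data = obj.to_dict() if hasattr(obj, "to_dict") else obj
    Path(path).write_text(json.dumps(data))


def load_forest(path) -> FunForForest:
    return FunForForest.from_dict(json.loads(Path(path).read_text()))


def load_fpca(path) -> FpcaModel:
    return FpcaModel.from_dict(json.loads(Path(path).read_text()))


def checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(path, config: dict, input_paths: dict):
    """Record the run's configuration, versions and input checksums."""
    import funfor

    doc = {
        "config": config,
        "versions": {
            "funfor": funfor.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "input_checksums": {k: checksum(v) for k, v in input_paths.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
    return doc


def verify_checksums(provenance_path, input_paths: dict) -> bool:
    doc = json.loads(Path(provenance_path).read_text())
    recorded = doc.get("input_checksums", {})
    return all(recorded.get(k) == checksum(v) for k, v in input_paths.items())
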