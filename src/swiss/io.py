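"""Readers and writers for plain-text expression matrices and label tables.

The on-disk contract is deliberately minimal: a matrix is a rectangular
TSV/CSV table with feature ids in the first column and sample ids in the
header row; labels are a two-column table of (sample id, class label).
Vendor formats (GCT, SOFT, CEL, ...) belong to upstream preprocessing
and are out of scope.  Delimiters are inferred from the file extension
(``.csv`` -> comma, anything else -> tab) and can be overridden.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import ClassAssignment, ExpressionMatrix

__all__ = ["read_matrix", "write_matrix", "read_labels", "write_labels", "file_checksum"]

PathLike = Union[str, Path]

# conventional header words for the two label columns
_SAMPLE_HEADERS = {"sample", "sample_id", "sampleid", "id", "array"}
_CLASS_HEADERS = {"class", "label", "group", "phenotype", "condition"}


def _delimiter(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: PathLike, delimiter: Optional[str] = None) -> ExpressionMatrix:
    """Read a features x samples matrix from a delimited text file.

    First column = feature id, header row = sample ids.  Decimal points
    only (no locale commas).  Errors pinpoint the offending cell by
    feature and sample id.
    """
    path = Path(path)
    sep = _delimiter(path, delimiter)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, header=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty matrix file") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from None
    if raw.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (wrong delimiter?)")
    if raw.index.has_duplicates:
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValueError(f"{path}: duplicate feature ids: {', '.join(map(str, dups))}")
    if raw.columns.has_duplicates:
        dups = sorted(set(raw.columns[raw.columns.duplicated()]))
        raise ValueError(f"{path}: duplicate sample ids: {', '.join(map(str, dups))}")
    values = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = values.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        feature, sample = raw.index[i], raw.columns[j]
        cell = raw.iat[i, j]
        what = "missing value" if cell is None or pd.isna(cell) else f"non-numeric value {cell!r}"
        raise ValueError(f"{path}: {what} at feature {feature!r}, sample {sample!r}")
    return ExpressionMatrix.from_dataframe(values)


def write_matrix(X: ExpressionMatrix, path: PathLike, delimiter: Optional[str] = None) -> None:
    """Write a matrix in the same dialect :func:`read_matrix` reads."""
    path = Path(path)
    X.to_dataframe().to_csv(path, sep=_delimiter(path, delimiter), index_label="feature_id")


def _looks_like_header(first_row: tuple[str, str]) -> bool:
    a, b = (f.strip().lower() for f in first_row)
    return a in _SAMPLE_HEADERS or b in _CLASS_HEADERS


def read_labels(path: PathLike, delimiter: Optional[str] = None) -> ClassAssignment:
    """Read a two-column (sample id, class label) table.

    A header row is optional and recognized by conventional column names
    (sample/sample_id/id..., class/label/group...).  Class order is
    first-appearance order, which affects reporting only, never scores.
    """
    path = Path(path)
    sep = _delimiter(path, delimiter)
    try:
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty label file") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from None
    if raw.shape[1] != 2:
        raise ValueError(f"{path}: label table must have exactly 2 columns, found {raw.shape[1]}")
    if raw.isna().to_numpy().any():
        row = int(np.argwhere(raw.isna().to_numpy())[0][0]) + 1
        raise ValueError(f"{path}: missing field on line {row}")
    rows = list(raw.itertuples(index=False, name=None))
    if _looks_like_header(rows[0]):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: label file contains a header but no data rows")
    return ClassAssignment.from_pairs((s.strip(), c.strip()) for s, c in rows)


def write_labels(C: ClassAssignment, path: PathLike, delimiter: Optional[str] = None) -> None:
    path = Path(path)
    sep = _delimiter(path, delimiter)
    with open(path, "w") as fh:
        fh.write(f"sample_id{sep}class\n")
        for sid, lab in C.labels.items():
            fh.write(f"{sid}{sep}{lab}\n")


def file_checksum(path: PathLike) -> str:
    """MD5 hex digest of a file, for provenance logging in reports."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
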