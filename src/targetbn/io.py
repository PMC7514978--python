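"""Readers for CSV and ARFF tables of labeled discrete data.

Both readers map ``?`` (and empty cells) to the missing marker, infer
categorical domains from the observed values in stable sorted order, and
leave id-like columns alone — dropping them is the caller's decision.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as _scipy_arff

from .data import (
    CATEGORICAL,
    CONTINUOUS,
    AttributeSchema,
    DiscreteDataset,
    SchemaError,
)


class FormatError(ValueError):
    """Raised when an input stream cannot be parsed in the named format."""


def _is_integral(series: pd.Series) -> bool:
    vals = series.dropna()
    if vals.empty:
        return True
    return bool(np.all(np.mod(vals.astype(float), 1) == 0))


def _encode_frame(
    df: pd.DataFrame,
    class_column,
    continuous_columns: Sequence[str] | None,
    kinds: dict[str, str] | None = None,
) -> DiscreteDataset:
    if isinstance(class_column, int):
        if not -df.shape[1] <= class_column < df.shape[1]:
            raise SchemaError(f"class column index {class_column} out of range")
        class_column = df.columns[class_column]
    if class_column not in df.columns:
        raise SchemaError(f"class column {class_column!r} not found")
    if df.shape[0] == 0:
        raise SchemaError("empty table")

    y_raw = df[class_column]
    if y_raw.isna().any():
        raise SchemaError("missing values in the class column")
    class_domain = tuple(sorted(y_raw.unique(), key=str))
    class_index = {c: i for i, c in enumerate(class_domain)}
    labels = y_raw.map(class_index).to_numpy(dtype=int)

    attr_cols = [c for c in df.columns if c != class_column]
    schema: list[AttributeSchema] = []
    rows = np.empty((df.shape[0], len(attr_cols)), dtype=float)
    for j, col in enumerate(attr_cols):
        series = df[col]
        if kinds is not None:
            kind = kinds[col]
        elif continuous_columns is not None:
            kind = CONTINUOUS if col in continuous_columns else CATEGORICAL
        else:
            # numeric with fractional values -> continuous; all else categorical
            numeric = pd.api.types.is_numeric_dtype(series)
            kind = CONTINUOUS if numeric and not _is_integral(series) else CATEGORICAL
        if kind == CONTINUOUS:
            schema.append(AttributeSchema(str(col), CONTINUOUS, (), j))
            rows[:, j] = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
        else:
            seen = series.dropna().unique()
            try:
                domain = tuple(sorted(seen))
            except TypeError:  # mixed types
                domain = tuple(sorted(seen, key=str))
            if not domain:
                raise SchemaError(f"attribute {col!r} has no observed values")
            index = {v: k for k, v in enumerate(domain)}
            codes = series.map(index)
            rows[:, j] = codes.to_numpy(dtype=float)
            schema.append(AttributeSchema(str(col), CATEGORICAL, domain, j))
    return DiscreteDataset(schema, rows, labels, class_domain)


def load_dataset(
    source,
    format: str = "csv",
    class_column=-1,
    continuous_columns: Sequence[str] | None = None,
    drop_columns: Sequence[str] = (),
    header: bool = True,
    names: Sequence[str] | None = None,
) -> DiscreteDataset:
    """Read a labeled table from a path or text stream.

    Parameters
    ----------
    source : path or file-like
    format : {"csv", "arff"}
    class_column : column name or integer position
        Position is resolved on the frame *after* ``drop_columns``.
    continuous_columns : optional explicit list of continuous columns (CSV);
        ARFF declares types itself.  When omitted, numeric columns with
        fractional values are treated as continuous.
    drop_columns : columns to discard before encoding (e.g. sample ids).
    """
    if format == "csv":
        try:
            df = pd.read_csv(
                source,
                header=0 if header else None,
                names=list(names) if names is not None else None,
                na_values=["?"],
                skipinitialspace=True,
            )
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"cannot parse CSV input: {exc}") from exc
        kinds = None
    elif format == "arff":
        try:
            if isinstance(source, (str, Path)):
                raw, meta = _scipy_arff.loadarff(str(source))
            else:
                raw, meta = _scipy_arff.loadarff(source)
        except Exception as exc:
            raise FormatError(f"cannot parse ARFF input: {exc}") from exc
        df = pd.DataFrame(raw)
        kinds = {}
        for col in df.columns:
            if meta[col][0] == "nominal":
                vals = df[col].str.decode("utf-8")
                df[col] = vals.where(vals != "?", other=pd.NA)
                kinds[col] = CATEGORICAL
            else:
                kinds[col] = CONTINUOUS
    else:
        raise FormatError(f"unknown format {format!r}")

    if drop_columns:
        df = df.drop(columns=list(drop_columns))
    if kinds is not None:
        kinds = {c: kinds[c] for c in df.columns}
    return _encode_frame(df, class_column, continuous_columns, kinds)


#: Column layout of the UCI "Breast Cancer Wisconsin (Original)" file.
WBC_COLUMNS = (
    "Sample code number",
    "Clump Thickness",
    "Cell Size",
    "Cell Shape",
    "Marginal Adhesion",
    "Epithelial Cell Size",
    "Bare Nuclei",
    "Bland Chromatin",
    "Normal Nucleoli",
    "Mitoses",
    "Class",
)


def load_wbc(path) -> DiscreteDataset:
    """Load the UCI Wisconsin breast cancer (Original) table.

    Expects the headerless ``breast-cancer-wisconsin.data`` file (11 comma
    separated columns).  The sample id column is dropped, leaving 9
    ten-valued attributes and the benign(2)/malignant(4) class.
    """
    return load_dataset(
        path,
        format="csv",
        header=False,
        names=WBC_COLUMNS,
        drop_columns=("Sample code number",),
        class_column="Class",
    )


def read_text(text: str, **kwargs) -> DiscreteDataset:
    """Convenience: parse an in-memory CSV/ARFF string."""
    return load_dataset(_io.StringIO(text), **kwargs)
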