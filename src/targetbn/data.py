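"""Core tabular containers for discrete classification data.

A :class:`DiscreteDataset` holds an ``N x n`` matrix of attribute values
together with a class label per row.  Categorical cells are stored as
0-based integer codes into the attribute's domain; continuous cells (only
present before discretization) are stored as raw floats.  Missing cells
are ``NaN`` internally; :meth:`DiscreteDataset.codes` exposes the fully
discrete view with ``MISSING`` (= -1) as the marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Missing-value marker in integer-coded attribute matrices.
MISSING: int = -1

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"


class SchemaError(ValueError):
    """Raised when a dataset violates its schema contract."""


@dataclass(frozen=True)
class AttributeSchema:
    """Description of one predictive attribute.

    Parameters
    ----------
    name : str
        Attribute name (column header).
    kind : {"categorical", "continuous"}
    domain : tuple
        Ordered admissible category codes; empty for continuous attributes.
    index : int
        0-based position of the attribute in the row matrix.
    """

    name: str
    kind: str
    domain: tuple = ()
    index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, CONTINUOUS):
            raise SchemaError(f"unknown attribute kind {self.kind!r}")
        if self.kind == CATEGORICAL and len(self.domain) == 0:
            raise SchemaError(f"categorical attribute {self.name!r} has empty domain")

    @property
    def cardinality(self) -> int:
        return len(self.domain)


@dataclass
class DiscreteDataset:
    """A labeled table of (mostly) categorical attributes.

    ``rows`` is a float matrix: categorical columns hold integer codes
    (exactly representable), continuous columns hold raw values, and NaN
    marks a missing cell in either case.
    """

    schema: list[AttributeSchema]
    rows: np.ndarray
    labels: np.ndarray
    class_domain: tuple

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.rows.ndim != 2:
            raise SchemaError("rows must be a 2-D matrix")
        if self.rows.shape[0] < 1:
            raise SchemaError("dataset must contain at least one row")
        if self.rows.shape[0] != self.labels.shape[0]:
            raise SchemaError("rows and labels disagree on N")
        if self.rows.shape[1] != len(self.schema):
            raise SchemaError("rows and schema disagree on n")
        indices = [a.index for a in self.schema]
        if sorted(indices) != list(range(len(self.schema))):
            raise SchemaError("schema indices must be unique and contiguous")
        m = len(self.class_domain)
        if m < 1:
            raise SchemaError("class domain is empty")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= m:
            raise SchemaError("label code outside class domain")
        for a in self.schema:
            if a.kind == CATEGORICAL:
                col = self.rows[:, a.index]
                seen = col[~np.isnan(col)]
                if seen.size and (seen.min() < 0 or seen.max() >= a.cardinality):
                    raise SchemaError(f"code outside domain for attribute {a.name!r}")

    # -- shape accessors -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.rows.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_domain)

    @property
    def is_discrete(self) -> bool:
        return all(a.kind == CATEGORICAL for a in self.schema)

    def domain_sizes(self) -> np.ndarray:
        """Cardinalities of the categorical attribute domains."""
        if not self.is_discrete:
            raise SchemaError("dataset still has continuous attributes")
        return np.array([a.cardinality for a in self.schema], dtype=int)

    def codes(self) -> np.ndarray:
        """Integer-coded matrix with ``MISSING`` for absent cells."""
        if not self.is_discrete:
            raise SchemaError("dataset still has continuous attributes")
        out = np.where(np.isnan(self.rows), MISSING, self.rows)
        return out.astype(int)

    def n_missing(self) -> int:
        return int(np.isnan(self.rows).sum())

    def take(self, indices: Sequence[int]) -> "DiscreteDataset":
        """Row subset (copy), preserving schema and class domain."""
        idx = np.asarray(indices, dtype=int)
        return replace(self, rows=self.rows[idx].copy(), labels=self.labels[idx].copy())

    def copy(self) -> "DiscreteDataset":
        return replace(self, rows=self.rows.copy(), labels=self.labels.copy())

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


def from_codes(
    codes: np.ndarray,
    labels: np.ndarray,
    domain_sizes: Sequence[int],
    class_domain: Sequence | None = None,
    names: Sequence[str] | None = None,
) -> DiscreteDataset:
    """Build a fully categorical dataset from an integer-coded matrix.

    ``MISSING`` (or any negative) entries become missing cells.  Domains are
    ``0..size-1`` per attribute; useful for synthetic data and tests.
    """
    codes = np.asarray(codes)
    n = codes.shape[1]
    names = list(names) if names is not None else [f"X{i + 1}" for i in range(n)]
    schema = [
        AttributeSchema(names[i], CATEGORICAL, tuple(range(int(domain_sizes[i]))), i)
        for i in range(n)
    ]
    rows = codes.astype(float)
    rows[codes < 0] = np.nan
    labels = np.asarray(labels, dtype=int)
    if class_domain is None:
        class_domain = tuple(range(int(labels.max()) + 1)) if labels.size else (0,)
    return DiscreteDataset(schema, rows, labels, tuple(class_domain))
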