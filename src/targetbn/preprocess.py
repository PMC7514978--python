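"""Preprocessing: imputation, discretization, oversampling, folds, missingness.

All randomness is routed through one explicit integer seed per operation so
every preprocessing step is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .data import CATEGORICAL, CONTINUOUS, AttributeSchema, DiscreteDataset, SchemaError


class ImputationError(ValueError):
    pass


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def column_fill_values(ds: DiscreteDataset) -> np.ndarray:
    """Training-time fill value per column: categorical mode (ties -> lowest
    code), continuous mean."""
    fills = np.empty(ds.n_attributes)
    for a in ds.schema:
        col = ds.rows[:, a.index]
        seen = col[~np.isnan(col)]
        if seen.size == 0:
            raise ImputationError(f"attribute {a.name!r} is entirely missing")
        if a.kind == CATEGORICAL:
            counts = np.bincount(seen.astype(int), minlength=a.cardinality)
            fills[a.index] = int(np.argmax(counts))  # argmax takes lowest tie
        else:
            fills[a.index] = seen.mean()
    return fills


def impute_training(ds: DiscreteDataset) -> DiscreteDataset:
    """Replace missing cells with the column mode (categorical) or mean
    (continuous), both estimated from the dataset itself."""
    if ds.n_missing() == 0:
        return ds
    fills = column_fill_values(ds)
    rows = ds.rows.copy()
    mask = np.isnan(rows)
    rows[mask] = np.broadcast_to(fills, rows.shape)[mask]
    return replace(ds, rows=rows)


def apply_fill_values(ds: DiscreteDataset, fills: np.ndarray) -> DiscreteDataset:
    """Impute with *given* (training-derived) fill values; used on test folds."""
    rows = ds.rows.copy()
    mask = np.isnan(rows)
    rows[mask] = np.broadcast_to(fills, rows.shape)[mask]
    return replace(ds, rows=rows)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _mdl_cuts(values: np.ndarray, labels: np.ndarray, m: int) -> list[float]:
    """Fayyad–Irani recursive entropy partitioning with the MDL stop rule."""
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]

    def recurse(lo: int, hi: int) -> list[float]:
        seg_v, seg_y = v[lo:hi], y[lo:hi]
        n = hi - lo
        if n < 2:
            return []
        total_counts = np.bincount(seg_y, minlength=m)
        ent = _entropy(total_counts)
        # candidate cuts at boundaries between distinct values
        best = None
        left_counts = np.zeros(m)
        for t in range(1, n):
            left_counts[seg_y[t - 1]] += 1
            if seg_v[t] == seg_v[t - 1]:
                continue
            right_counts = total_counts - left_counts
            gain = ent - (t / n) * _entropy(left_counts) - ((n - t) / n) * _entropy(
                right_counts
            )
            if best is None or gain > best[0]:
                best = (gain, t, _entropy(left_counts), _entropy(right_counts),
                        left_counts.copy(), right_counts.copy())
        if best is None:
            return []
        gain, t, ent_l, ent_r, cl, cr = best
        k_all = int((total_counts > 0).sum())
        k_l = int((cl > 0).sum())
        k_r = int((cr > 0).sum())
        delta = np.log2(3 ** k_all - 2) - (k_all * ent - k_l * ent_l - k_r * ent_r)
        threshold = (np.log2(n - 1) + delta) / n
        if gain <= threshold:
            return []
        cut = (seg_v[t - 1] + seg_v[t]) / 2.0
        return recurse(lo, lo + t) + [cut] + recurse(lo + t, hi)

    return recurse(0, len(v))


def discretize(
    ds: DiscreteDataset, method: str = "mdl", bins: int = 5
) -> DiscreteDataset:
    """Replace continuous columns by categorical bin codes.

    ``mdl`` performs supervised entropy/MDL binning on the class; columns
    where MDL finds no informative cut collapse to a single bin.
    ``equal_frequency`` uses ``bins`` quantile bins.
    """
    if ds.is_discrete:
        return ds
    if method not in ("mdl", "equal_frequency"):
        raise ParameterError(f"unknown discretization method {method!r}")
    if method == "equal_frequency" and bins < 2:
        raise ParameterError("equal_frequency needs bins >= 2")

    rows = ds.rows.copy()
    schema = list(ds.schema)
    for a in ds.schema:
        if a.kind != CONTINUOUS:
            continue
        col = rows[:, a.index]
        present = ~np.isnan(col)
        vals = col[present]
        if vals.size == 0:
            raise ImputationError(f"attribute {a.name!r} is entirely missing")
        if method == "mdl":
            cuts = _mdl_cuts(vals, ds.labels[present], ds.n_classes)
        else:
            qs = np.quantile(vals, np.linspace(0, 1, bins + 1)[1:-1])
            cuts = sorted(set(float(q) for q in qs))
        codes = np.searchsorted(np.asarray(cuts), vals, side="right")
        n_bins = len(cuts) + 1
        newcol = np.full_like(col, np.nan)
        newcol[present] = codes
        rows[:, a.index] = newcol
        schema[a.index] = AttributeSchema(
            a.name, CATEGORICAL, tuple(range(n_bins)), a.index
        )
    return DiscreteDataset(schema, rows, ds.labels.copy(), ds.class_domain)


# ---------------------------------------------------------------------------
# class balancing
# ---------------------------------------------------------------------------

def oversample(ds: DiscreteDataset, seed: int = 0) -> DiscreteDataset:
    """Replicate seeded random minority-class rows until every class count
    equals the majority count.  All original rows are retained."""
    if ds.n_classes < 2:
        raise ParameterError("oversampling needs at least two classes")
    counts = ds.class_counts()
    if (counts == 0).any():
        raise ParameterError("a class has zero instances")
    target = counts.max()
    if (counts == target).all():
        return ds
    rng = np.random.default_rng(seed)
    extra = []
    for c in range(ds.n_classes):
        need = target - counts[c]
        if need > 0:
            pool = np.flatnonzero(ds.labels == c)
            extra.append(rng.choice(pool, size=need, replace=True))
    idx = np.concatenate([np.arange(ds.n_rows)] + extra)
    return ds.take(idx)


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

def make_folds(
    ds: DiscreteDataset, folds: int = 10, rounds: int = 20, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold assignments for repeated k-fold cross-validation.

    Returns ``rounds * folds`` (train_indices, test_indices) pairs.  Within
    each round the test sets partition ``0..N-1`` with sizes differing by at
    most one; stratification deals each class's shuffled rows round-robin
    across folds, rotating the starting fold so totals stay balanced.
    """
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    if folds > ds.n_rows:
        raise ParameterError("more folds than rows")
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    n = ds.n_rows
    for _ in range(rounds):
        assignment = np.empty(n, dtype=int)
        offset = 0
        for c in range(ds.n_classes):
            pool = np.flatnonzero(ds.labels == c)
            rng.shuffle(pool)
            assignment[pool] = (offset + np.arange(pool.size)) % folds
            offset = (offset + pool.size) % folds
        for f in range(folds):
            test = np.flatnonzero(assignment == f)
            train = np.flatnonzero(assignment != f)
            out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# controlled missingness
# ---------------------------------------------------------------------------

def inject_missing(ds: DiscreteDataset, rate: float, seed: int = 0) -> DiscreteDataset:
    """Delete ``round(rate * n)`` attribute cells per row, uniformly without
    replacement; labels are untouched."""
    if not 0 <= rate < 1:
        raise ParameterError("rate must be in [0, 1)")
    per_row = int(round(rate * ds.n_attributes))
    if per_row == 0:
        return ds
    rng = np.random.default_rng(seed)
    rows = ds.rows.copy()
    for r in range(ds.n_rows):
        cols = rng.choice(ds.n_attributes, size=per_row, replace=False)
        rows[r, cols] = np.nan
    return replace(ds, rows=rows)
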