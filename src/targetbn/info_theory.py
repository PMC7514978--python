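"""Sufficient statistics and dependence criteria for discrete BNCs.

One pass over the training rows fills a :class:`CountCache` with class,
(value, class) and unordered (value, value, class) co-occurrence counts.
Every dependence measure — mutual information I(X;C), conditional mutual
information I(Xi;Xj|C), their value-level (local) analogues I(x;C) and
I(xi;xj|C), and the pointwise variants — is a closed-form function of that
cache under maximum-likelihood probabilities.  Each measure derives its
marginals from its own contingency table, so the decomposition identities

    I(Xi;C)    = sum_{xi} I(xi;C)
    I(Xi;Xj|C) = sum_{xi,xj} I(xi;xj|C)

hold exactly, including in the presence of missing cells (a pair count
requires both cells present; such rows drop out of both sides).

Probabilities here are deliberately unsmoothed: smoothing would bias the
rankings used for structure learning.  0*log(0) terms contribute 0; the
default logarithm base is 2 (scores in bits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import MISSING, DiscreteDataset


class ParameterError(ValueError):
    pass


@dataclass
class CountCache:
    """Co-occurrence sufficient statistics for a discrete labeled table.

    ``pair_counts`` is stored once per unordered attribute pair ``(i, j)``
    with ``i < j``; :meth:`pair` handles symmetric access.
    """

    n_total: int
    class_counts: np.ndarray                    # (m,)
    value_counts: list[np.ndarray]              # per attr: (v_i, m)
    pair_counts: dict[tuple[int, int], np.ndarray]  # (i,j) i<j: (v_i, v_j, m)
    domain_sizes: np.ndarray
    log_base: float = 2.0

    @property
    def n_attributes(self) -> int:
        return len(self.value_counts)

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)

    def pair(self, i: int, j: int) -> np.ndarray:
        """Pair table with axes ordered (v_i, v_j, class)."""
        if i == j:
            raise ParameterError("attribute pair requires i != j")
        if i < j:
            return self.pair_counts[(i, j)]
        return self.pair_counts[(j, i)].transpose(1, 0, 2)

    def copy(self) -> "CountCache":
        return CountCache(
            self.n_total,
            self.class_counts.copy(),
            [t.copy() for t in self.value_counts],
            {k: t.copy() for k, t in self.pair_counts.items()},
            self.domain_sizes.copy(),
            self.log_base,
        )


def build_counts(ds: DiscreteDataset, log_base: float = 2.0) -> CountCache:
    """Tally the sufficient statistics in one pass over the rows.

    Only non-missing cells are counted; a pair count requires both cells of
    the pair to be present in the row.
    """
    if ds.n_rows < 1:
        raise ParameterError("empty dataset")
    codes = ds.codes()
    y = ds.labels
    m = ds.n_classes
    sizes = ds.domain_sizes()
    n = ds.n_attributes

    class_counts = np.bincount(y, minlength=m).astype(np.int64)
    value_counts = []
    present = codes != MISSING
    for i in range(n):
        tab = np.zeros((sizes[i], m), dtype=np.int64)
        mask = present[:, i]
        np.add.at(tab, (codes[mask, i], y[mask]), 1)
        value_counts.append(tab)
    pair_counts: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n):
        for j in range(i + 1, n):
            tab = np.zeros((sizes[i], sizes[j], m), dtype=np.int64)
            mask = present[:, i] & present[:, j]
            np.add.at(tab, (codes[mask, i], codes[mask, j], y[mask]), 1)
            pair_counts[(i, j)] = tab
    return CountCache(ds.n_rows, class_counts, value_counts, pair_counts,
                      sizes, log_base)


# ---------------------------------------------------------------------------
# average (distribution-level) measures
# ---------------------------------------------------------------------------

def _plogr(p: np.ndarray, num: np.ndarray, den: np.ndarray, base: float) -> np.ndarray:
    """p * log(num/den) with 0*log(.) := 0."""
    out = np.zeros_like(p, dtype=float)
    mask = p > 0
    out[mask] = p[mask] * (np.log(num[mask]) - np.log(den[mask]))
    return out / np.log(base)


def mutual_information(cache: CountCache, i: int) -> float:
    """I(Xi; C) from the (value, class) contingency table (Eq. of MI)."""
    tab = cache.value_counts[i].astype(float)
    tot = tab.sum()
    if tot == 0:
        return 0.0
    p = tab / tot
    pi = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    return float(_plogr(p, p, pi * pc, cache.log_base).sum())


def conditional_mutual_information(cache: CountCache, i: int, j: int) -> float:
    """I(Xi; Xj | C), symmetric in (i, j), nonnegative up to rounding."""
    tab = cache.pair(i, j).astype(float)
    tot = tab.sum()
    if tot == 0:
        return 0.0
    p = tab / tot
    pc = p.sum(axis=(0, 1), keepdims=True)          # P(c)
    pic = p.sum(axis=1, keepdims=True)              # P(xi, c)
    pjc = p.sum(axis=0, keepdims=True)              # P(xj, c)
    return float(_plogr(p, p * pc, pic * pjc, cache.log_base).sum())


def local_mutual_information(cache: CountCache, i: int, v_i: int) -> float:
    """LMI I(xi; C) = sum_c P(c, xi) log[P(c, xi) / (P(c) P(xi))].

    Value-level slice of MI; may be negative.  A value with zero count
    contributes nothing and yields 0.
    """
    tab = cache.value_counts[i].astype(float)
    tot = tab.sum()
    if tot == 0:
        return 0.0
    p = tab / tot
    row = p[v_i]                                   # P(xi, c) over c
    pv = row.sum()
    pc = p.sum(axis=0)
    return float(_plogr(row, row, pv * pc, cache.log_base).sum())


def conditional_local_mutual_information(
    cache: CountCache, i: int, v_i: int, j: int, v_j: int
) -> float:
    """CLMI I(xi; xj | C) = sum_c P(xi,xj,c) log[P(xi,xj|c)/(P(xi|c)P(xj|c))]."""
    if i == j:
        raise ParameterError("CLMI requires i != j")
    tab = cache.pair(i, j).astype(float)
    tot = tab.sum()
    if tot == 0:
        return 0.0
    p = tab / tot
    cell = p[v_i, v_j]                             # P(xi, xj, c) over c
    pc = p.sum(axis=(0, 1))
    pic = p.sum(axis=1)[v_i]                       # P(xi, c)
    pjc = p.sum(axis=0)[v_j]                       # P(xj, c)
    return float(_plogr(cell, cell * pc, pic * pjc, cache.log_base).sum())


# ---------------------------------------------------------------------------
# rankings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DependenceRanking:
    """Per-attribute scores with the induced descending order.

    Ties are broken by ascending attribute index.  Attributes excluded from
    the ranking (missing values in an instance-level ranking) carry a NaN
    score and are absent from ``order``.
    """

    scores: np.ndarray
    order: tuple


def _rank(scores: np.ndarray, eligible: np.ndarray) -> tuple:
    idx = np.flatnonzero(eligible)
    order = sorted(idx, key=lambda a: (-scores[a], a))
    return tuple(int(a) for a in order)


def scmi_ranking(cache: CountCache) -> DependenceRanking:
    """SCMI(Xi) = sum_{j != i} I(Xi; Xj | C), sorted descending."""
    n = cache.n_attributes
    if n < 2:
        raise ParameterError("SCMI needs at least two attributes")
    scores = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            cmi = conditional_mutual_information(cache, i, j)
            scores[i] += cmi
            scores[j] += cmi
    return DependenceRanking(scores, _rank(scores, np.ones(n, dtype=bool)))


def sclmi_ranking(cache: CountCache, instance: np.ndarray) -> DependenceRanking:
    """SCLMI(xi) = sum_{j != i} I(xi; xj | C) over the instance's values.

    Attributes whose value is missing in the instance are excluded from the
    order and from every sum — dependence relationships touching missing
    values are simply not considered.
    """
    instance = np.asarray(instance, dtype=int)
    n = cache.n_attributes
    if instance.shape != (n,):
        raise ParameterError("instance length must equal attribute count")
    present = instance != MISSING
    if not present.any():
        raise ParameterError("all instance values are missing")
    scores = np.full(n, np.nan)
    scores[present] = 0.0
    idx = np.flatnonzero(present)
    for a, i in enumerate(idx):
        for j in idx[a + 1:]:
            clmi = conditional_local_mutual_information(
                cache, i, int(instance[i]), int(j), int(instance[j])
            )
            scores[i] += clmi
            scores[j] += clmi
    return DependenceRanking(scores, _rank(np.nan_to_num(scores, nan=-np.inf), present))


# ---------------------------------------------------------------------------
# pointwise variants
# ---------------------------------------------------------------------------

def pointwise_mi(cache: CountCache, i: int, v: int, c: int) -> float:
    """PMI(x; c) = log[P(x, c) / (P(x) P(c))]; -inf when the joint is empty."""
    tab = cache.value_counts[i].astype(float)
    tot = tab.sum()
    joint = tab[v, c] / tot
    pv = tab[v].sum() / tot
    pc = tab[:, c].sum() / tot
    if joint == 0 or pv == 0 or pc == 0:
        warnings.warn("zero probability in PMI ratio; returning -inf")
        return -np.inf
    return float(np.log(joint / (pv * pc)) / np.log(cache.log_base))


def pointwise_cmi(cache: CountCache, i: int, v_i: int, j: int, v_j: int, c: int) -> float:
    """PCMI(xi; xj | c) = log[P(xi,xj|c) / (P(xi|c) P(xj|c))]."""
    if i == j:
        raise ParameterError("PCMI requires i != j")
    tab = cache.pair(i, j).astype(float)
    nc = tab[:, :, c].sum()
    if nc == 0:
        warnings.warn("empty class in PCMI; returning -inf")
        return -np.inf
    joint = tab[v_i, v_j, c] / nc
    pi = tab[v_i, :, c].sum() / nc
    pj = tab[:, v_j, c].sum() / nc
    if joint == 0 or pi == 0 or pj == 0:
        warnings.warn("zero probability in PCMI ratio; returning -inf")
        return -np.inf
    return float(np.log(joint / (pi * pj)) / np.log(cache.log_base))


def cmi_matrix(cache: CountCache) -> np.ndarray:
    """Symmetric matrix of pairwise CMI values (diagonal 0)."""
    n = cache.n_attributes
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = conditional_mutual_information(cache, i, j)
    return out


def mi_vector(cache: CountCache) -> np.ndarray:
    return np.array([mutual_information(cache, i) for i in range(cache.n_attributes)])
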