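"""Parameter estimation and log-domain posterior inference.

CPTs are estimated with additive (Laplace) smoothing,

    P(x_i | pa, c) = (count(x_i, pa, c) + alpha) / (count(pa, c) + alpha * v_i),

with ``alpha = 0`` giving maximum likelihood and a uniform fallback on
parent configurations never seen in training.  For unrestricted (UKDB)
structures the class factor is P(c | x_p) estimated from (x_p-configuration,
class) counts; P(x_p) itself is never parameterized since it cancels in the
argmax.  All scoring is done in the log domain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import MISSING, DiscreteDataset
from .info_theory import CountCache, ParameterError
from .structure import BNCStructure


@dataclass
class CPTSet:
    """Smoothed conditional probability tables for one structure.

    ``attr_tables[i]`` has axes ``(*parent domains, class, child domain)``
    and is normalized over the last axis.  ``class_table`` is P(c) for
    restricted structures or P(c | x_p) with axes ``(*xp domains, class)``
    for unrestricted ones.  ``class_marginal`` (plain P(c)) backs up the
    class factor when an x_p value is missing at query time.
    """

    attr_tables: dict = field(default_factory=dict)
    class_table: np.ndarray | None = None
    class_marginal: np.ndarray | None = None
    alpha: float = 1.0


@dataclass
class BNCModel:
    structure: BNCStructure
    cpts: CPTSet
    domain_sizes: np.ndarray
    n_classes: int

    def to_json(self) -> str:
        doc = {
            "format": "targetbn-model/1",
            "structure": json.loads(self.structure.to_json()),
            "alpha": self.cpts.alpha,
            "domain_sizes": [int(v) for v in self.domain_sizes],
            "n_classes": self.n_classes,
            "class_table": self.cpts.class_table.tolist(),
            "class_marginal": self.cpts.class_marginal.tolist(),
            "attr_tables": {str(i): t.tolist() for i, t in self.cpts.attr_tables.items()},
        }
        return json.dumps(doc)


def _smooth(counts: np.ndarray, alpha: float) -> np.ndarray:
    """Normalize over the last axis with additive smoothing; empty
    configurations fall back to uniform."""
    v = counts.shape[-1]
    num = counts + alpha
    den = num.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    uniform = np.full(v, 1.0 / v)
    empty = counts.sum(axis=-1) == 0
    if alpha == 0 and empty.any():
        out[empty] = uniform
    return out


def fit_cpts(
    structure: BNCStructure,
    ds: DiscreteDataset,
    alpha: float = 1.0,
) -> BNCModel:
    """Estimate all conditional probability tables for ``structure``.

    Rows with a missing value in a factor's child or parents are excluded
    from that factor's counts only.
    """
    codes = ds.codes()
    y = ds.labels
    m = ds.n_classes
    sizes = ds.domain_sizes()
    if structure.n != ds.n_attributes:
        raise ParameterError("structure and dataset disagree on attribute count")

    cpts = CPTSet(alpha=alpha)
    cpts.class_marginal = _smooth(
        np.bincount(y, minlength=m).astype(float), alpha
    )
    if structure.xp:
        shape = tuple(int(sizes[p]) for p in structure.xp) + (m,)
        counts = np.zeros(shape)
        mask = np.all(codes[:, list(structure.xp)] != MISSING, axis=1)
        idx = tuple(codes[mask, p] for p in structure.xp) + (y[mask],)
        np.add.at(counts, idx, 1)
        cpts.class_table = _smooth(counts, alpha)
    else:
        cpts.class_table = cpts.class_marginal

    for i in structure.attr_order:
        pa = structure.parents[i]
        shape = tuple(int(sizes[p]) for p in pa) + (m, int(sizes[i]))
        counts = np.zeros(shape)
        cols = list(pa) + [i]
        mask = np.all(codes[:, cols] != MISSING, axis=1)
        idx = tuple(codes[mask, p] for p in pa) + (y[mask], codes[mask, i])
        np.add.at(counts, idx, 1)
        cpts.attr_tables[i] = _smooth(counts, alpha)
    return BNCModel(structure, cpts, sizes, m)


# ---------------------------------------------------------------------------
# pseudo-instance augmentation (target learning)
# ---------------------------------------------------------------------------

def augment_pseudo(cache: CountCache, instance: np.ndarray) -> CountCache:
    """Add the m pseudo instances for a testing target to a count cache.

    The unlabeled instance is copied once per class label with unit weight,
    so every value it carries — including values unseen in training — gets a
    well-defined count in the LMI/CLMI statistics.  The input cache is not
    modified.
    """
    instance = np.asarray(instance, dtype=int)
    out = cache.copy()
    m = cache.n_classes
    out.n_total += m
    out.class_counts += 1
    present = np.flatnonzero(instance != MISSING)
    for i in present:
        out.value_counts[i][instance[i], :] += 1
    for a, i in enumerate(present):
        for j in present[a + 1:]:
            out.pair_counts[(int(i), int(j))][instance[i], instance[j], :] += 1
    return out


# ---------------------------------------------------------------------------
# posterior queries
# ---------------------------------------------------------------------------

def log_posterior(model: BNCModel, instance: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class log scores and the softmax-normalized posterior.

    Factors whose child value or any parent value is missing are skipped;
    if the x_p configuration is incomplete the class factor falls back to
    the marginal P(c).  If every attribute factor is skipped the posterior
    degrades to the (possibly marginal) class factor alone; a fully
    uninformative query warns and returns uniform.
    """
    instance = np.asarray(instance, dtype=int)
    s = model.structure
    cpts = model.cpts
    m = model.n_classes

    used = 0
    if s.xp and np.all(instance[list(s.xp)] != MISSING):
        idx = tuple(int(instance[p]) for p in s.xp)
        scores = np.log(cpts.class_table[idx])
        used += 1
    else:
        scores = np.log(cpts.class_marginal)
        if not s.xp:
            used += 1
    for i in s.attr_order:
        pa = s.parents[i]
        if instance[i] == MISSING or any(instance[p] == MISSING for p in pa):
            continue
        idx = tuple(int(instance[p]) for p in pa) + (slice(None), int(instance[i]))
        scores = scores + np.log(cpts.attr_tables[i][idx])
        used += 1
    if used == 0:
        warnings.warn("all factors skipped; returning uniform posterior")
        scores = np.zeros(m)
    shifted = scores - scores.max()
    post = np.exp(shifted)
    post /= post.sum()
    return scores, post


def ensemble_posterior(p_t: np.ndarray, p_p: np.ndarray) -> np.ndarray:
    """Uniformly weighted average of the two sub-model posteriors."""
    p_t = np.asarray(p_t, dtype=float)
    p_p = np.asarray(p_p, dtype=float)
    if p_t.shape != p_p.shape:
        raise ParameterError("posterior length mismatch")
    return (p_t + p_p) / 2.0


def predict(posterior: np.ndarray) -> int:
    """Argmax class; ties break to the lowest class index."""
    posterior = np.asarray(posterior)
    if posterior.size == 0:
        raise ParameterError("empty posterior")
    return int(np.argmax(posterior))
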