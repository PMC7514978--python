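"""Synthetic discrete-data generators with known (planted) structure.

The generator samples from a k-dependence Bayesian network whose shape
matches the unrestricted classifiers: a hub set of ``k_true`` attributes is
coupled to the class and serves as shared parent of every other attribute.
Each conditional table interpolates between uniform and a seeded
permutation-peaked table via the coupling strength ``theta``:

    table = (1 - theta) * uniform + theta * onehot(peak(config))

so ``theta = 0`` gives mutual conditional independence and ``theta -> 1``
near-deterministic parent-child coupling, with the exact Bayes error
computable by enumeration for small n and v.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .data import MISSING, DiscreteDataset, from_codes
from .info_theory import ParameterError
from .structure import BNCStructure


@dataclass(frozen=True)
class GeneratorSpec:
    """Stated world of one synthetic dataset family.

    Defaults emulate a small clinical-table shape: a handful of few-valued
    discrete attributes, a mildly imbalanced binary class, and one planted
    dependence hub.
    """

    n: int = 5
    v: int = 3
    m: int = 2
    k_true: int = 1
    theta: float = 0.7
    class_prior: tuple = (0.655, 0.345)
    n_rows: int = 1000
    seed: int = 0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2 or self.v < 2 or self.m < 2:
            raise ParameterError("need n >= 2, v >= 2, m >= 2")
        if not 0 <= self.theta <= 1:
            raise ParameterError("theta must lie in [0, 1]")
        if not 1 <= self.k_true < self.n:
            raise ParameterError("need 1 <= k_true < n")
        if len(self.class_prior) != self.m or abs(sum(self.class_prior) - 1) > 1e-9:
            raise ParameterError("class prior must have m entries summing to 1")


@dataclass
class BNGenerator:
    """A sampled ground-truth network: structure plus sampling tables.

    ``hub_tables[h]`` is P(x_h | c) for each hub attribute; ``child_tables[i]``
    has axes (*hub domains, class, child domain) for the remaining
    attributes.  Sampling is ancestral: class from the prior, hubs given the
    class, children given hubs and class.
    """

    spec: GeneratorSpec
    structure: BNCStructure
    prior: np.ndarray
    hub_tables: dict
    child_tables: dict

    def sample(self, n_rows: int, seed: int) -> DiscreteDataset:
        return sample_dataset(self, n_rows, seed)

    # -- exact quantities by enumeration --------------------------------
    def joint(self) -> np.ndarray:
        """Exact joint P(x1..xn, c) as an (v, .., v, m) array (small n only)."""
        sp = self.spec
        if sp.v ** sp.n * sp.m > 2_000_000:
            raise ParameterError("joint enumeration too large")
        shape = (sp.v,) * sp.n + (sp.m,)
        out = np.empty(shape)
        hubs = list(self.structure.xp)
        rest = [i for i in range(sp.n) if i not in hubs]
        for x in product(range(sp.v), repeat=sp.n):
            for c in range(sp.m):
                p = self.prior[c]
                for h in hubs:
                    p *= self.hub_tables[h][c, x[h]]
                hv = tuple(x[h] for h in hubs)
                for i in rest:
                    p *= self.child_tables[i][hv + (c, x[i])]
                out[x + (c,)] = p
        return out

    def bayes_error(self) -> float:
        """Exact error of the Bayes-optimal rule under the true joint."""
        joint = self.joint()
        flat = joint.reshape(-1, self.spec.m)
        return float((flat.sum(axis=1) - flat.max(axis=1)).sum())


def _peaked_tables(rng: np.random.Generator, shape_cfg: tuple, v: int,
                   theta: float) -> np.ndarray:
    """Tables of shape (*shape_cfg, v): uniform/peak mixture, peak value
    drawn per configuration from a seeded permutation-style assignment."""
    n_cfg = int(np.prod(shape_cfg)) if shape_cfg else 1
    peaks = rng.integers(0, v, size=n_cfg)
    # guarantee the peaks are not all identical (degenerate coupling)
    if v > 1 and n_cfg > 1 and np.all(peaks == peaks[0]):
        peaks[rng.integers(0, n_cfg)] = (peaks[0] + 1) % v
    tab = np.full((n_cfg, v), (1.0 - theta) / v)
    tab[np.arange(n_cfg), peaks] += theta
    return tab.reshape(shape_cfg + (v,))


def random_bn(spec: GeneratorSpec) -> BNGenerator:
    """Seeded random ground-truth network with the unrestricted-KDB shape."""
    rng = np.random.default_rng(spec.seed)
    hubs = tuple(sorted(rng.choice(spec.n, size=spec.k_true, replace=False)))
    rest = tuple(i for i in range(spec.n) if i not in hubs)
    structure = BNCStructure(
        n=spec.n, k=spec.k_true, xp=hubs, attr_order=rest,
        parents={i: hubs for i in rest},
    )
    prior = np.asarray(spec.class_prior, dtype=float)
    hub_tables = {
        h: _peaked_tables(rng, (spec.m,), spec.v, spec.theta) for h in hubs
    }
    child_tables = {
        i: _peaked_tables(rng, (spec.v,) * spec.k_true + (spec.m,), spec.v,
                          spec.theta)
        for i in rest
    }
    return BNGenerator(spec, structure, prior, hub_tables, child_tables)


def sample_dataset(gen: BNGenerator, n_rows: int, seed: int) -> DiscreteDataset:
    """Ancestral sampling from the generator; optional uniform missingness."""
    if n_rows < 1:
        raise ParameterError("need at least one row")
    sp = gen.spec
    rng = np.random.default_rng(seed)
    y = rng.choice(sp.m, size=n_rows, p=gen.prior)
    X = np.empty((n_rows, sp.n), dtype=int)
    hubs = list(gen.structure.xp)
    for h in hubs:
        cum = gen.hub_tables[h].cumsum(axis=1)
        u = rng.random(n_rows)
        X[:, h] = (u[:, None] > cum[y]).sum(axis=1)
    for i in gen.structure.attr_order:
        cfg = tuple(X[:, h] for h in hubs) + (y,)
        rows_p = gen.child_tables[i][cfg]          # (n_rows, v)
        u = rng.random(n_rows)
        X[:, i] = (u[:, None] > rows_p.cumsum(axis=1)).sum(axis=1)
    if sp.missing_rate > 0:
        per_row = int(round(sp.missing_rate * sp.n))
        for r in range(n_rows):
            cols = rng.choice(sp.n, size=per_row, replace=False)
            X[r, cols] = MISSING
    return from_codes(X, y, [sp.v] * sp.n)


def wbc_like(seed: int = 0) -> DiscreteDataset:
    """A 699-row table shaped like the Wisconsin breast cancer database.

    Nine attributes valued 1..10 (codes 0..9), binary class with a
    65.5/34.5 prior, one strongly coupled attribute pair (attributes 1 and
    2) and 16 missing cells planted in attribute 6 — mirroring the shape,
    imbalance and missingness pattern of the clinical table without
    emulating its distribution.
    """
    rng = np.random.default_rng(seed)
    n, v, n_rows = 9, 10, 699
    prior = np.array([0.655, 0.345])
    y = rng.choice(2, size=n_rows, p=prior)
    X = np.empty((n_rows, n), dtype=int)
    # attribute 0 (Clump Thickness analogue): class-coupled, theta=0.6
    t0 = _peaked_tables(rng, (2,), v, 0.6)
    # attribute 1 tracks attribute 0 tightly (the planted dependence)
    t1 = _peaked_tables(rng, (v, 2), v, 0.85)
    # remaining attributes: weak class coupling, conditionally independent
    others = {i: _peaked_tables(rng, (2,), v, 0.3) for i in range(2, n)}

    def draw(tab_rows: np.ndarray) -> np.ndarray:
        u = rng.random(tab_rows.shape[0])
        return (u[:, None] > tab_rows.cumsum(axis=1)).sum(axis=1)

    X[:, 0] = draw(t0[y])
    X[:, 1] = draw(t1[X[:, 0], y])
    for i in range(2, n):
        X[:, i] = draw(others[i][y])
    miss_rows = rng.choice(n_rows, size=16, replace=False)
    X[miss_rows, 5] = MISSING
    names = [
        "Clump Thickness", "Cell Size", "Cell Shape", "Marginal Adhesion",
        "Epithelial Cell Size", "Bare Nuclei", "Bland Chromatin",
        "Normal Nucleoli", "Mitoses",
    ]
    return from_codes(X, y, [v] * n, names=names)
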