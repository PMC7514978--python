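"""Structure learning for restricted and unrestricted k-dependence BNCs.

All learners are deterministic functions of a :class:`CountCache`:

* ``learn_nb`` — no attribute-attribute edges (0-dependence).
* ``learn_tan`` — Chow–Liu maximum-weight spanning tree on pairwise CMI,
  directed away from the attribute with maximal MI with the class.
* ``learn_kdb`` — Sahami's scheme: attributes sorted by descending I(Xi;C),
  each taking the k strongest earlier attributes (by CMI) as parents.
* ``learn_ukdb_t`` — the unrestricted variant: the k attributes with the
  largest SCMI form the Markov-blanket parent set X_p (parents of the class
  and candidate parents of everything else); every remaining attribute gets
  exactly k attribute-parents chosen by CMI from X_p and earlier attributes.
* ``learn_ukdb_p`` — the per-instance analogue, replacing SCMI/CMI with
  SCLMI/CLMI evaluated at the instance's attribute values; attributes whose
  value is missing are left out of the structure entirely.

Every tie — in MI, CMI, SCMI, SCLMI or tree edge weight — is broken by
ascending attribute index, so learned structures are reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data import MISSING
from .info_theory import (
    CountCache,
    ParameterError,
    cmi_matrix,
    conditional_local_mutual_information,
    mi_vector,
    scmi_ranking,
    sclmi_ranking,
)


@dataclass
class BNCStructure:
    """DAG over {C, X_1..X_n} in classifier-factored form.

    ``xp`` lists the parents of the class (empty for NB/TAN/KDB).  For every
    attribute in ``attr_order``, ``parents[i]`` lists its attribute-parents;
    the class is implicitly a parent of every non-``xp`` attribute.
    Attributes absent from both ``xp`` and ``attr_order`` (possible only for
    instance-specific structures) contribute no factor.
    """

    n: int
    k: int
    xp: tuple = ()
    attr_order: tuple = ()
    parents: dict = field(default_factory=dict)
    instance_bound: np.ndarray | None = None

    def __post_init__(self) -> None:
        if set(self.xp) & set(self.attr_order):
            raise ParameterError("xp and attr_order overlap")
        for i, pa in self.parents.items():
            allowed = set(self.xp) | set(
                self.attr_order[: self.attr_order.index(i)]
            )
            if not set(pa) <= allowed:
                raise ParameterError(f"parent of X{i} outside candidate set")

    @property
    def attributes(self) -> tuple:
        return tuple(self.xp) + tuple(self.attr_order)

    def attribute_edges(self) -> list[tuple[int, int]]:
        """Directed attribute-attribute edges (parent, child)."""
        return [(p, i) for i in self.attr_order for p in self.parents[i]]

    @property
    def n_attribute_edges(self) -> int:
        return len(self.attribute_edges())

    def to_networkx(self) -> nx.DiGraph:
        """Full DAG including the class node ``"C"``."""
        g = nx.DiGraph()
        g.add_node("C")
        for i in range(self.n):
            g.add_node(i)
        for p in self.xp:
            g.add_edge(p, "C")
        for i in self.attr_order:
            g.add_edge("C", i)
            for p in self.parents[i]:
                g.add_edge(p, i)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def to_dot(self, names: list[str] | None = None) -> str:
        names = names or [f"X{i + 1}" for i in range(self.n)]
        lines = ["digraph bnc {", '  C [shape=doublecircle];']
        for u, v in self.to_networkx().edges:
            su = "C" if u == "C" else names[u]
            sv = "C" if v == "C" else names[v]
            lines.append(f'  "{su}" -> "{sv}";')
        lines.append("}")
        return "\n".join(lines)

    def to_json(self, names: list[str] | None = None) -> str:
        names = names or [f"X{i + 1}" for i in range(self.n)]
        doc = {
            "n": self.n,
            "k": self.k,
            "xp": [names[i] for i in self.xp],
            "order": [names[i] for i in self.attr_order],
            "parents": {names[i]: [names[p] for p in self.parents[i]]
                        for i in self.attr_order},
        }
        if self.instance_bound is not None:
            doc["instance"] = [int(v) for v in self.instance_bound]
        return json.dumps(doc, indent=2)


# ---------------------------------------------------------------------------
# restricted classifiers
# ---------------------------------------------------------------------------

def learn_nb(n: int) -> BNCStructure:
    """Naive Bayes: class is sole parent of every attribute."""
    return BNCStructure(n=n, k=0, attr_order=tuple(range(n)),
                        parents={i: () for i in range(n)})


def learn_tan(cache: CountCache) -> BNCStructure:
    """Chow–Liu tree-augmented naive Bayes.

    Kruskal on descending CMI with (weight, low index) tie order; edges are
    then directed away from the root, chosen as the attribute with maximal
    MI with the class.
    """
    n = cache.n_attributes
    if n < 2:
        raise ParameterError("TAN needs at least two attributes")
    w = cmi_matrix(cache)
    edges = sorted(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (-w[e], e[0], e[1]),
    )
    parent_of = list(range(n))  # union-find

    def find(a: int) -> int:
        while parent_of[a] != a:
            parent_of[a] = parent_of[parent_of[a]]
            a = parent_of[a]
        return a

    tree: dict[int, list[int]] = {i: [] for i in range(n)}
    taken = 0
    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent_of[ri] = rj
            tree[i].append(j)
            tree[j].append(i)
            taken += 1
            if taken == n - 1:
                break

    mi = mi_vector(cache)
    root = int(min(range(n), key=lambda a: (-mi[a], a)))
    parents: dict[int, tuple] = {root: ()}
    order = [root]
    stack = [root]
    seen = {root}
    while stack:
        u = stack.pop()
        for v in sorted(tree[u]):
            if v not in seen:
                seen.add(v)
                parents[v] = (u,)
                order.append(v)
                stack.append(v)
    return BNCStructure(n=n, k=1, attr_order=tuple(order), parents=parents)


def learn_kdb(cache: CountCache, k: int) -> BNCStructure:
    """Sahami's k-dependence classifier structure."""
    if k < 0:
        raise ParameterError("k must be >= 0")
    n = cache.n_attributes
    mi = mi_vector(cache)
    order = sorted(range(n), key=lambda a: (-mi[a], a))
    w = cmi_matrix(cache) if k > 0 else None
    parents: dict[int, tuple] = {}
    for pos, i in enumerate(order):
        earlier = order[:pos]
        if k == 0:
            parents[i] = ()
        elif len(earlier) <= k:
            parents[i] = tuple(earlier)
        else:
            chosen = sorted(earlier, key=lambda j: (-w[i, j], j))[:k]
            parents[i] = tuple(sorted(chosen, key=earlier.index))
    return BNCStructure(n=n, k=k, attr_order=tuple(order), parents=parents)


# ---------------------------------------------------------------------------
# unrestricted (Markov-blanket) classifiers
# ---------------------------------------------------------------------------

def select_xp(cache: CountCache, k: int) -> tuple:
    """The k attributes with the largest SCMI, in descending SCMI order."""
    n = cache.n_attributes
    if not 1 <= k < n:
        raise ParameterError("need 1 <= k < n for X_p selection")
    return scmi_ranking(cache).order[:k]


def _ukdb_scheme(
    n: int, k: int, xp: tuple, rest: tuple, weight
) -> dict[int, tuple]:
    """Shared UKDB parent assignment: attribute at each position takes the k
    strongest candidates among xp and earlier attributes."""
    parents: dict[int, tuple] = {}
    for pos, i in enumerate(rest):
        candidates = list(xp) + list(rest[:pos])
        if len(candidates) <= k:
            parents[i] = tuple(candidates)
        else:
            chosen = sorted(candidates, key=lambda j: (-weight(i, j), j))[:k]
            parents[i] = tuple(sorted(chosen, key=candidates.index))
    return parents


def learn_ukdb_t(cache: CountCache, k: int) -> BNCStructure:
    """Training-set unrestricted KDB.

    X_p (top-k SCMI) becomes parent of the class; the remaining attributes,
    ordered by descending SCMI, each take exactly k attribute-parents chosen
    by CMI from {X_p, earlier attributes}.
    """
    n = cache.n_attributes
    if not 1 <= k < n:
        raise ParameterError("need 1 <= k < n")
    ranking = scmi_ranking(cache)
    xp = ranking.order[:k]
    rest = ranking.order[k:]
    w = cmi_matrix(cache)
    parents = _ukdb_scheme(n, k, xp, rest, lambda i, j: w[i, j])
    return BNCStructure(n=n, k=k, xp=xp, attr_order=rest, parents=parents)


def learn_ukdb_p(cache: CountCache, instance: np.ndarray, k: int) -> BNCStructure:
    """Instance-specific unrestricted KDB (target learning).

    ``cache`` must already contain the m pseudo instances for this target
    (see :func:`targetbn.inference.augment_pseudo`).  SCLMI replaces SCMI
    for the ordering and X_p choice, CLMI replaces CMI for parent choice.
    Attributes with a missing value are excluded from the structure; if
    fewer than k+1 values are present, k degrades with a warning.
    """
    instance = np.asarray(instance, dtype=int)
    n = cache.n_attributes
    ranking = sclmi_ranking(cache, instance)
    available = len(ranking.order)
    if available - 1 < k:
        warnings.warn(
            f"only {available} non-missing values; degrading k to {available - 1}"
        )
        k = available - 1
    if k < 1:
        raise ParameterError("instance-specific structure needs k >= 1 after degradation")
    xp = ranking.order[:k]
    rest = ranking.order[k:]

    def clmi(i: int, j: int) -> float:
        return conditional_local_mutual_information(
            cache, i, int(instance[i]), j, int(instance[j])
        )

    parents = _ukdb_scheme(n, k, xp, rest, clmi)
    return BNCStructure(n=n, k=k, xp=xp, attr_order=rest, parents=parents,
                        instance_bound=instance)
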