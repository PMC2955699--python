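"""Counting and enumerating rooted leaf-labelled tree topologies.

Bifurcating topologies on ``n`` leaves are counted by the double factorial
``(2n-3)!!``.  Multifurcating topologies are counted by internal-node number
``m`` with the recursion

    T(n, m) = (n + m - 2) * T(n-1, m-1) + m * T(n-1, m),

seeded by ``T(1, 0) = 1``: the new leaf either subdivides one of the
``n + m - 2`` edges (creating a new internal node) or attaches to one of the
``m`` existing internal nodes.  ``enumerate_topologies`` realizes the same
insertion argument explicitly and serves as the brute-force oracle for both
the counts and the neighbour-graph diameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .topology import TreeTopology, _canonicalize, _raw_neighbours, max_score

__all__ = [
    "count_bifurcating",
    "count_multifurcating",
    "count_multifurcating_total",
    "enumerate_topologies",
    "neighbour_graph",
    "neighbour_graph_diameter",
    "TopologyCountTable",
    "count_table",
]

#: Largest n for which exhaustive enumeration is allowed (39,208 topologies).
MAX_ENUMERABLE = 7


def count_bifurcating(n: int) -> int:
    """Number of rooted bifurcating leaf-labelled topologies: ``(2n-3)!!``."""
    if n < 1:
        raise ValueError("need at least one species")
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out


@lru_cache(maxsize=None)
def count_multifurcating(n: int, m: int) -> int:
    """Number of rooted multifurcating topologies on ``n`` leaves with ``m``
    internal nodes; 0 outside ``1 <= m <= n-1`` (and ``T(1,0) = 1``)."""
    if n < 1:
        raise ValueError("need at least one species")
    if n == 1:
        return 1 if m == 0 else 0
    if m < 1 or m > n - 1:
        return 0
    return (n + m - 2) * count_multifurcating(n - 1, m - 1) + m * count_multifurcating(
        n - 1, m
    )


def count_multifurcating_total(n: int) -> int:
    """Total number of rooted multifurcating topologies on ``n`` leaves."""
    if n < 1:
        raise ValueError("need at least one species")
    return sum(count_multifurcating(n, m) for m in range(0, n))


def _insertions(node, label: str) -> list:
    """All raw trees obtained by inserting leaf ``label`` into ``node``:
    bracket with any subtree (subdividing its parent edge) or attach as an
    extra child of any internal node."""
    out = [(node, label)]
    if isinstance(node, tuple):
        out.append(node + (label,))
        for i, child in enumerate(node):
            for sub in _insertions(child, label):
                out.append(node[:i] + (sub,) + node[i + 1 :])
    return out


def enumerate_topologies(n: int) -> list[TreeTopology]:
    """All distinct rooted multifurcating topologies on labels ``1..n``.

    Refuses ``n > 7`` (the space grows super-exponentially).  Output is sorted
    by canonical text, so the enumeration order is deterministic.
    """
    if not 1 <= n <= MAX_ENUMERABLE:
        raise ValueError(f"enumeration supported for 1 <= n <= {MAX_ENUMERABLE}")
    current: dict[str, object] = {"1": "1"}
    for k in range(2, n + 1):
        label = str(k)
        grown: dict[str, object] = {}
        for node in current.values():
            for raw in _insertions(node, label):
                cn, text, _ = _canonicalize(raw)
                grown[text] = cn
        current = grown
    return [
        TreeTopology._from_canonical(cn, text)
        for text, cn in sorted(current.items())
    ]


def neighbour_graph(trees: list[TreeTopology]) -> csr_matrix:
    """Sparse adjacency matrix of the neighbour-move graph on ``trees``.

    ``trees`` must be closed under the move relation (e.g. a full
    enumeration); an unknown neighbour raises ``KeyError``.
    """
    index = {t.canonical_text: i for i, t in enumerate(trees)}
    rows, cols = [], []
    for i, t in enumerate(trees):
        if t.n_leaves < 3:
            continue
        for text, _ in _raw_neighbours(t.root):
            rows.append(i)
            cols.append(index[text])
    data = np.ones(len(rows), dtype=np.int8)
    return csr_matrix((data, (rows, cols)), shape=(len(trees), len(trees)))


def neighbour_graph_diameter(n: int) -> int:
    """Diameter (maximum pairwise edit distance) of the full neighbour graph
    on all rooted multifurcating topologies with ``n`` labelled leaves."""
    trees = enumerate_topologies(n)
    adj = neighbour_graph(trees)
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    if np.isinf(dist).any():
        raise RuntimeError("neighbour graph is disconnected")  # cannot happen
    return int(dist.max())


@dataclass(frozen=True)
class TopologyCountTable:
    """Topology counts for one species number ``n``."""

    n: int
    bifurcating: int
    multifurcating_by_internal: dict[int, int]
    multifurcating_total: int
    max_score: int | None

    def __post_init__(self):
        assert self.multifurcating_total == sum(
            self.multifurcating_by_internal.values()
        )


def count_table(n: int) -> TopologyCountTable:
    """Counts and maximum score for ``n`` species (max score undefined for n < 3)."""
    by_m = {m: count_multifurcating(n, m) for m in range(0, n)}
    by_m = {m: c for m, c in by_m.items() if c}
    return TopologyCountTable(
        n=n,
        bifurcating=count_bifurcating(n),
        multifurcating_by_internal=by_m,
        multifurcating_total=count_multifurcating_total(n),
        max_score=max_score(n) if n >= 3 else None,
    )
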