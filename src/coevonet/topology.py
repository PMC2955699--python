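"""Rooted multifurcating tree topologies and the neighbour-move edit distance.

A *topology* is a rooted, leaf-labelled tree without branch lengths in which
every internal node has at least two children.  Two topologies on the same
leaf set are *neighbours* if one can be obtained from the other by moving a
single species across an internal node.  The edit distance ``eta`` between two
topologies is the length of the shortest path in this neighbour graph, and the
similarity ``Gamma = 1 - eta / M_n`` normalizes it by the maximum achievable
distance ``M_n`` on ``n`` shared species, so that trees on different species
subsets become comparable.

The move set consists of four elementary rearrangements of a single leaf:

* PROMOTE - detach a leaf from its parent ``P`` and re-attach it to ``P``'s
  parent; if ``P`` is left with one child it is spliced out.
* DEMOTE - detach a leaf and re-attach it as an extra child of a sibling
  internal node.
* GROUP-LEAVES - bracket two sibling leaves under a new internal node, when
  their parent has at least three children.
* GROUP-LEAF-WITH-NODE - bracket a sibling {leaf, internal node} pair under a
  new internal node, when their parent has at least three children.

DEMOTE inverts PROMOTE when the old parent survives, and the two GROUP moves
invert it when the old parent was spliced, so the neighbour relation is
symmetric and the shortest-path distance is a metric.

Internally a topology is a nested structure of ``str`` (leaf label) and
``tuple`` (internal node, children in canonical order).  Canonical order sorts
children by (smallest leaf label, canonical text), which makes the canonical
text a unique key: two topologies are equal iff their canonical texts are.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Union

import dendropy

__all__ = [
    "TreeTopology",
    "ComparisonResult",
    "IncomparableTreesError",
    "UnresolvedDistanceError",
    "parse_topology",
    "restrict",
    "neighbours",
    "edit_distance",
    "max_score",
    "similarity",
    "compare",
]

#: Minimum number of shared species for a topology comparison to be defined.
MIN_SHARED_SPECIES = 3

#: Default cap on the number of states a distance search may generate.
DEFAULT_NODE_BUDGET = 2_000_000

Node = Union[str, tuple]


class IncomparableTreesError(ValueError):
    """Raised when two trees share fewer than three species."""


class UnresolvedDistanceError(RuntimeError):
    """Raised when a distance search exceeds its state budget."""


def _canonicalize(node: Node) -> tuple[Node, str, str]:
    """Return (canonical node, canonical text, smallest leaf label)."""
    if isinstance(node, str):
        return node, node, node
    triples = sorted((_canonicalize(c) for c in node), key=lambda t: (t[2], t[1]))
    kids = tuple(t[0] for t in triples)
    text = "(" + ",".join(t[1] for t in triples) + ")"
    return kids, text, triples[0][2]


def _splice(node) -> Node:
    """Normalize a raw nested structure: collapse unary nodes, tuple-ify."""
    if isinstance(node, str):
        return node
    kids = [_splice(c) for c in node]
    if not kids:
        raise ValueError("internal node with no children")
    if len(kids) == 1:
        return kids[0]
    return tuple(kids)


def _leaves(node: Node, out: list) -> list:
    if isinstance(node, str):
        out.append(node)
    else:
        for c in node:
            _leaves(c, out)
    return out


class TreeTopology:
    """A canonical rooted multifurcating leaf-labelled topology.

    Instances are immutable and hashable; equality is canonical-text equality,
    so child order in the input never matters.
    """

    __slots__ = ("root", "canonical_text", "leaf_set")

    def __init__(self, root):
        root = _splice(root)
        labels = _leaves(root, [])
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        if not all(labels):
            raise ValueError("empty leaf label")
        croot, text, _ = _canonicalize(root)
        object.__setattr__(self, "root", croot)
        object.__setattr__(self, "canonical_text", text)
        object.__setattr__(self, "leaf_set", frozenset(labels))

    @classmethod
    def _from_canonical(cls, croot: Node, text: str) -> "TreeTopology":
        """Trusted constructor for already-canonical internal structures."""
        t = object.__new__(cls)
        object.__setattr__(t, "root", croot)
        object.__setattr__(t, "canonical_text", text)
        object.__setattr__(t, "leaf_set", frozenset(_leaves(croot, [])))
        return t

    def __setattr__(self, *_):
        raise AttributeError("TreeTopology is immutable")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_set)

    def internal_node_count(self) -> int:
        def count(node: Node) -> int:
            if isinstance(node, str):
                return 0
            return 1 + sum(count(c) for c in node)

        return count(self.root)

    def is_bifurcating(self) -> bool:
        def ok(node: Node) -> bool:
            if isinstance(node, str):
                return True
            return len(node) == 2 and all(ok(c) for c in node)

        return ok(self.root)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TreeTopology):
            return NotImplemented
        return self.canonical_text == other.canonical_text

    def __hash__(self) -> int:
        return hash(self.canonical_text)

    def __repr__(self) -> str:
        return f"TreeTopology({self.canonical_text!r})"

    def __str__(self) -> str:
        return self.canonical_text


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of comparing two topologies on their shared species.

    ``status`` is ``"incomparable"`` when fewer than three species are shared;
    otherwise ``"match"`` (identical restricted topologies, ``eta == 0``) or
    ``"mismatch"``, with ``eta``, ``max_score`` and ``similarity`` filled in.
    """

    status: str
    shared_species_count: int
    eta: Optional[int] = None
    max_score: Optional[int] = None
    similarity: Optional[float] = None

    def __post_init__(self):
        if self.status not in ("match", "mismatch", "incomparable"):
            raise ValueError(f"bad status {self.status!r}")


def parse_topology(text: str) -> TreeTopology:
    """Parse a Newick-style topology string into a canonical :class:`TreeTopology`.

    Branch lengths and internal node labels are tolerated and discarded; a
    trailing semicolon is optional.  Raises ``ValueError`` on malformed input,
    duplicate leaf labels, or an empty tree.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty topology string")
    if not text.endswith(";"):
        text += ";"
    try:
        tree = dendropy.Tree.get(
            file=io.StringIO(text),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises many error types
        raise ValueError(f"malformed topology string: {exc}") from exc

    def convert(nd) -> Node:
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label is None or label == "":
                raise ValueError("leaf with empty label")
            return str(label)
        return [convert(c) for c in nd.child_nodes()]

    if tree.seed_node is None:
        raise ValueError("empty tree")
    return TreeTopology(convert(tree.seed_node))


def restrict(t: TreeTopology, keep: Iterable[str]) -> TreeTopology:
    """Restrict ``t`` to the leaves in ``keep``, splicing out unary nodes."""
    keep = frozenset(keep) & t.leaf_set
    if not keep:
        raise ValueError("restriction would remove every leaf")
    if keep == t.leaf_set:
        return t

    def prune(node: Node):
        if isinstance(node, str):
            return node if node in keep else None
        kids = [k for k in (prune(c) for c in node) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return tuple(kids)

    return TreeTopology(prune(t.root))


def _variants(node: Node) -> list:
    """Raw (non-canonical) results of one leaf move applied within ``node``."""
    out: list = []
    if isinstance(node, str):
        return out
    kids = node
    n = len(kids)
    for i, child in enumerate(kids):
        for alt in _variants(child):
            out.append(kids[:i] + (alt,) + kids[i + 1 :])
    # PROMOTE: a leaf inside an internal child climbs up to this node.
    for i, sub in enumerate(kids):
        if isinstance(sub, str):
            continue
        for j, leaf in enumerate(sub):
            if not isinstance(leaf, str):
                continue
            rest = sub[:j] + sub[j + 1 :]
            new_sub = rest[0] if len(rest) == 1 else rest
            out.append(kids[:i] + (new_sub,) + kids[i + 1 :] + (leaf,))
    # DEMOTE: a leaf child of this node drops into a sibling internal node.
    # Only legal when this node keeps >= 2 children: the spliced variant has
    # no inverse leaf move (its reversal would bracket two internal nodes),
    # and PROMOTE already generates the spliced outcome's topology.
    if n >= 3:
        for i, leaf in enumerate(kids):
            if not isinstance(leaf, str):
                continue
            for j, sub in enumerate(kids):
                if i == j or isinstance(sub, str):
                    continue
                rem = tuple(kids[k] for k in range(n) if k not in (i, j))
                out.append(rem + (sub + (leaf,),))
    # GROUP: bracket a sibling pair containing at least one leaf.
    if n >= 3:
        for i in range(n):
            for j in range(i + 1, n):
                if not (isinstance(kids[i], str) or isinstance(kids[j], str)):
                    continue
                rem = tuple(kids[k] for k in range(n) if k not in (i, j))
                out.append(rem + ((kids[i], kids[j]),))
    return out


@lru_cache(maxsize=131072)
def _raw_neighbours(croot: Node) -> tuple[tuple[str, Node], ...]:
    """Canonical neighbours of a canonical node as (text, node) pairs.

    Memoized: ensemble runs compare thousands of tree pairs whose searches
    revisit the same region of topology space, so neighbour sets recur.
    """
    found: dict[str, Node] = {}
    for var in _variants(croot):
        cn, text, _ = _canonicalize(var)
        found[text] = cn
    _, self_text, _ = _canonicalize(croot)
    found.pop(self_text, None)
    return tuple(found.items())


def neighbours(t: TreeTopology) -> frozenset[TreeTopology]:
    """All topologies exactly one leaf move away from ``t``.

    The relation is symmetric: ``t`` is a neighbour of each returned tree.
    Requires at least three leaves (smaller topologies are unique).
    """
    if t.n_leaves < MIN_SHARED_SPECIES:
        raise ValueError("neighbour moves need at least 3 leaves")
    return frozenset(
        TreeTopology._from_canonical(cn, text)
        for text, cn in _raw_neighbours(t.root)
    )


def max_score(n: int) -> int:
    """Maximum edit distance ``M_n`` between two topologies on ``n`` species.

    ``M_n = 1 + (n-1)(n-2)/2``, anchored at ``M_3 = 2``; equals the diameter
    of the neighbour graph (verified exhaustively for n <= 6 in the tests).
    """
    if n < MIN_SHARED_SPECIES:
        raise ValueError(f"max score undefined for n={n} < 3 species")
    return 1 + (n - 1) * (n - 2) // 2


def _bfs_distance(a: TreeTopology, b: TreeTopology, node_budget: int) -> int:
    """Shortest neighbour-path length between two same-leaf-set topologies.

    Bidirectional breadth-first search over canonical texts.  Layers advance
    alternately on the smaller frontier; meetings are collected per layer and
    the minimum over a completed layer is the exact distance.
    """
    if a.canonical_text == b.canonical_text:
        return 0
    visited_a: dict[str, int] = {a.canonical_text: 0}
    visited_b: dict[str, int] = {b.canonical_text: 0}
    frontier_a: dict[str, Node] = {a.canonical_text: a.root}
    frontier_b: dict[str, Node] = {b.canonical_text: b.root}
    depth_a = depth_b = 0
    expanded = 0
    bound = max_score(a.n_leaves)
    while frontier_a and frontier_b:
        if len(frontier_a) <= len(frontier_b):
            frontier, visited, other, depth = frontier_a, visited_a, visited_b, depth_a
        else:
            frontier, visited, other, depth = frontier_b, visited_b, visited_a, depth_b
        new_frontier: dict[str, Node] = {}
        best = None
        for node in frontier.values():
            for text, cn in _raw_neighbours(node):
                if text in visited:
                    continue
                expanded += 1
                if expanded > node_budget:
                    raise UnresolvedDistanceError(
                        f"distance search exceeded budget of {node_budget} states"
                    )
                visited[text] = depth + 1
                if text in other:
                    cand = depth + 1 + other[text]
                    if best is None or cand < best:
                        best = cand
                new_frontier[text] = cn
        if best is not None:
            return best
        if frontier is frontier_a:
            frontier_a, depth_a = new_frontier, depth_a + 1
        else:
            frontier_b, depth_b = new_frontier, depth_b + 1
        if depth_a + depth_b > bound:  # unreachable for a connected move graph
            raise UnresolvedDistanceError("search exceeded the theoretical diameter")
    raise UnresolvedDistanceError("neighbour graph frontier exhausted without meeting")


def _restrict_to_shared(a: TreeTopology, b: TreeTopology) -> tuple[TreeTopology, TreeTopology, int]:
    shared = a.leaf_set & b.leaf_set
    n = len(shared)
    if n < MIN_SHARED_SPECIES:
        raise IncomparableTreesError(
            f"trees share only {n} species; at least {MIN_SHARED_SPECIES} required"
        )
    return restrict(a, shared), restrict(b, shared), n


def edit_distance(
    a: TreeTopology,
    b: TreeTopology,
    *,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> int:
    """Edit distance ``eta``: minimum number of leaf moves between ``a`` and
    ``b`` after restriction to their shared species.

    Raises :class:`IncomparableTreesError` if fewer than three species are
    shared, and :class:`UnresolvedDistanceError` if the search state budget
    is exhausted (only plausible for very distant trees on >7 species).
    """
    ra, rb, _ = _restrict_to_shared(a, b)
    return _bfs_distance(ra, rb, node_budget)


def similarity(
    a: TreeTopology,
    b: TreeTopology,
    *,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> float:
    """Similarity ``Gamma = 1 - eta / M_n`` on the ``n`` shared species."""
    ra, rb, n = _restrict_to_shared(a, b)
    eta = _bfs_distance(ra, rb, node_budget)
    return 1.0 - eta / max_score(n)


def compare(
    a: TreeTopology,
    b: TreeTopology,
    *,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> ComparisonResult:
    """Full comparison of two topologies; never raises on disjoint leaf sets."""
    shared = a.leaf_set & b.leaf_set
    n = len(shared)
    if n < MIN_SHARED_SPECIES:
        return ComparisonResult(status="incomparable", shared_species_count=n)
    ra, rb = restrict(a, shared), restrict(b, shared)
    eta = _bfs_distance(ra, rb, node_budget)
    m = max_score(n)
    return ComparisonResult(
        status="match" if eta == 0 else "mismatch",
        shared_species_count=n,
        eta=eta,
        max_score=m,
        similarity=1.0 - eta / m,
    )
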