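"""Structured random-graph null models for protein interaction networks.

Five ensembles, each preserving different features of the empirical graph
``G`` (always its node set and edge count, never mutating the input):

* ``random_graph`` - Erdos-Renyi G(n, m): m distinct edges placed uniformly
  at random; node traits stay on their nodes.
* ``node_shuffle`` - the adjacency matrix is kept, the node trait bundles
  (tree, profile, classes) are permuted uniformly over all nodes.
* ``network_shuffle`` - degree-preserving rewiring by repeated double-edge
  swaps; traits stay on their nodes, so each node keeps both its degree and
  its biology.
* ``bio_node_shuffle`` - trait permutation restricted to nodes sharing the
  same class label for a chosen characteristic.
* ``bio_network_shuffle`` - double-edge swaps additionally constrained so
  each replacement edge has the same edge class as the edge it replaces,
  where the edge class is the unordered pair of endpoint labels.

Swap chains are run for ``swaps_per_edge * m`` accepted swaps per sample
(default 10), with rejected proposals resampled; this is the standard mixing
heuristic, not an exactly-uniform sampler of the constrained graph space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Optional

import networkx as nx
import numpy as np

from .graphio import ProteinGraph

__all__ = [
    "EnsembleSpec",
    "MODELS",
    "sample_random_graph",
    "sample_node_shuffle",
    "sample_network_shuffle",
    "sample_bio_node_shuffle",
    "sample_bio_network_shuffle",
    "sample_ensemble",
]

logger = logging.getLogger(__name__)

MODELS = (
    "random_graph",
    "node_shuffle",
    "network_shuffle",
    "bio_node_shuffle",
    "bio_network_shuffle",
)
_BIO_MODELS = ("bio_node_shuffle", "bio_network_shuffle")

#: Node attribute keys treated as the permutable trait bundle.
TRAIT_KEYS = ("tree", "profile", "classes")


@dataclass(frozen=True)
class EnsembleSpec:
    """Which null model to sample, and how."""

    model: str
    characteristic: Optional[str] = None
    samples: int = 1000
    seed: Optional[int] = None
    swaps_per_edge: int = 10

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.model in _BIO_MODELS and not self.characteristic:
            raise ValueError(f"model {self.model!r} requires a characteristic")
        if self.model not in _BIO_MODELS and self.characteristic:
            raise ValueError(f"model {self.model!r} takes no characteristic")
        if self.samples < 1:
            raise ValueError("samples must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


def _nodes(g: ProteinGraph) -> list:
    return sorted(g.nodes())


def _structure_copy(g: ProteinGraph, with_edges: bool) -> ProteinGraph:
    """New graph sharing node attribute values (never mutated downstream)."""
    h = nx.Graph()
    for v in _nodes(g):
        h.add_node(v, **g.nodes[v])
    if with_edges:
        h.add_edges_from(g.edges())
    return h


def sample_random_graph(g: ProteinGraph, rng: np.random.Generator) -> ProteinGraph:
    """Uniform simple graph with the same nodes (and traits) and edge count."""
    nodes = _nodes(g)
    n = len(nodes)
    m = g.number_of_edges()
    if m > n * (n - 1) // 2:
        raise ValueError("more edges requested than distinct node pairs")
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < m:
        need = m - len(chosen)
        ii = rng.integers(0, n, size=2 * need + 4)
        jj = rng.integers(0, n, size=2 * need + 4)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            e = (i, j) if i < j else (j, i)
            chosen.add(e)
            if len(chosen) == m:
                break
    h = _structure_copy(g, with_edges=False)
    h.add_edges_from((nodes[i], nodes[j]) for i, j in chosen)
    return h


def _permute_traits(
    g: ProteinGraph, nodes: list, perm: np.ndarray
) -> ProteinGraph:
    h = _structure_copy(g, with_edges=True)
    for i, v in enumerate(nodes):
        src = g.nodes[nodes[perm[i]]]
        for key in TRAIT_KEYS:
            h.nodes[v].pop(key, None)
            if key in src:
                h.nodes[v][key] = src[key]
    return h


def sample_node_shuffle(g: ProteinGraph, rng: np.random.Generator) -> ProteinGraph:
    """Keep the adjacency matrix, permute trait bundles uniformly over nodes."""
    nodes = _nodes(g)
    perm = rng.permutation(len(nodes))
    return _permute_traits(g, nodes, perm)


def _node_class(g: ProteinGraph, v, characteristic: str) -> str:
    classes = g.nodes[v].get("classes") or {}
    return classes.get(characteristic, "unknown")


def _require_characteristic(g: ProteinGraph, characteristic: str) -> None:
    if not any(
        characteristic in (g.nodes[v].get("classes") or {}) for v in g.nodes
    ):
        raise ValueError(f"characteristic {characteristic!r} not found on any node")


def sample_bio_node_shuffle(
    g: ProteinGraph, characteristic: str, rng: np.random.Generator
) -> ProteinGraph:
    """Trait permutation restricted to within-class exchanges.

    Nodes without a label for ``characteristic`` form the class ``"unknown"``.
    """
    _require_characteristic(g, characteristic)
    nodes = _nodes(g)
    perm = np.arange(len(nodes))
    by_class: dict[str, list[int]] = {}
    for i, v in enumerate(nodes):
        by_class.setdefault(_node_class(g, v, characteristic), []).append(i)
    for members in by_class.values():
        idx = np.array(members)
        perm[idx] = idx[rng.permutation(len(idx))]
    return _permute_traits(g, nodes, perm)


def _swap_chain(
    g: ProteinGraph,
    rng: np.random.Generator,
    swaps_per_edge: int,
    edge_class,
) -> ProteinGraph:
    """Double-edge-swap rewiring; ``edge_class`` of each replaced edge must be
    preserved (pass a constant function for the unconstrained chain)."""
    m = g.number_of_edges()
    if m < 2:
        return _structure_copy(g, with_edges=True)
    edges = [tuple(e) for e in g.edges()]
    eset = {frozenset(e) for e in edges}
    # The random parity bit matters on tiny constrained instances, where a
    # fixed accepted-swap count would deterministically fix which half of the
    # graph space a sample can land in (the chain toggles between states).
    quota = swaps_per_edge * m + int(rng.integers(2))
    cap = 100 * quota
    accepted = 0
    attempts = 0
    while accepted < quota and attempts < cap:
        attempts += 1
        i = int(rng.integers(0, m))
        j = int(rng.integers(0, m))
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose replacing (a,b),(c,d) by (a,d),(c,b)
        if a == d or c == b:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in eset or new2 in eset:
            continue
        if edge_class(a, d) != edge_class(a, b) or edge_class(c, b) != edge_class(c, d):
            continue
        eset.discard(frozenset((a, b)))
        eset.discard(frozenset((c, d)))
        eset.add(new1)
        eset.add(new2)
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1
    if accepted < quota:
        logger.warning(
            "swap chain stopped at %d/%d accepted swaps after %d attempts "
            "(heavily constrained instance)",
            accepted,
            quota,
            attempts,
        )
    h = _structure_copy(g, with_edges=False)
    h.add_edges_from(edges)
    return h


def sample_network_shuffle(
    g: ProteinGraph, rng: np.random.Generator, swaps_per_edge: int = 10
) -> ProteinGraph:
    """Degree-preserving rewiring: every node keeps its degree and traits."""
    return _swap_chain(g, rng, swaps_per_edge, edge_class=lambda u, v: None)


def sample_bio_network_shuffle(
    g: ProteinGraph,
    characteristic: str,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> ProteinGraph:
    """Degree-preserving rewiring that also preserves each edge's class, the
    unordered pair of endpoint labels for ``characteristic``."""
    _require_characteristic(g, characteristic)
    labels = {v: _node_class(g, v, characteristic) for v in g.nodes}

    def edge_class(u, v):
        lu, lv = labels[u], labels[v]
        return (lu, lv) if lu <= lv else (lv, lu)

    return _swap_chain(g, rng, swaps_per_edge, edge_class=edge_class)


def sample_ensemble(g: ProteinGraph, spec: EnsembleSpec) -> Iterator[ProteinGraph]:
    """Yield ``spec.samples`` graphs from the chosen ensemble, deterministic
    under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.samples):
        if spec.model == "random_graph":
            yield sample_random_graph(g, rng)
        elif spec.model == "node_shuffle":
            yield sample_node_shuffle(g, rng)
        elif spec.model == "network_shuffle":
            yield sample_network_shuffle(g, rng, spec.swaps_per_edge)
        elif spec.model == "bio_node_shuffle":
            yield sample_bio_node_shuffle(g, spec.characteristic, rng)
        else:
            yield sample_bio_network_shuffle(
                g, spec.characteristic, rng, spec.swaps_per_edge
            )
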