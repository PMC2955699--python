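"""Null-model samplers: constraint preservation, support, uniformity."""

from collections import Counter

import networkx as nx
import numpy as np
import pytest
from scipy.stats import binom

from coevonet import (
    EnsembleSpec,
    sample_bio_network_shuffle,
    sample_bio_node_shuffle,
    sample_ensemble,
    sample_network_shuffle,
    sample_node_shuffle,
    sample_random_graph,
)


def traited_path(labels=("x", "y", "z", "w"), classes=("a", "a", "b", "b")):
    g = nx.Graph()
    nodes = ["n1", "n2", "n3", "n4"][: len(labels)]
    for v, trait, cls in zip(nodes, labels, classes):
        g.add_node(v, tree=trait, classes={"process": cls})
    g.add_edges_from(zip(nodes, nodes[1:]))
    return g


def edge_key(g):
    return frozenset(frozenset(e) for e in g.edges())


def binom_band(n, p, alpha=0.01):
    return binom.ppf(alpha / 2, n, p), binom.ppf(1 - alpha / 2, n, p)


class TestCommonInvariants:
    @pytest.fixture()
    def g(self, small_dataset):
        return small_dataset.graph

    @pytest.mark.parametrize(
        "draw",
        [
            lambda g, r: sample_random_graph(g, r),
            lambda g, r: sample_node_shuffle(g, r),
            lambda g, r: sample_network_shuffle(g, r),
            lambda g, r: sample_bio_node_shuffle(g, "process", r),
            lambda g, r: sample_bio_network_shuffle(g, "process", r),
        ],
        ids=["random", "node", "network", "bio_node", "bio_network"],
    )
    def test_order_size_simplicity_and_no_mutation(self, g, draw):
        before_edges = edge_key(g)
        before_traits = {v: dict(g.nodes[v]) for v in g.nodes}
        rng = np.random.default_rng(11)
        for _ in range(5):
            h = draw(g, rng)
            assert set(h.nodes) == set(g.nodes)
            assert h.number_of_edges() == g.number_of_edges()
            assert not any(u == v for u, v in h.edges())
        assert edge_key(g) == before_edges
        assert {v: dict(g.nodes[v]) for v in g.nodes} == before_traits


class TestRandomGraph:
    def test_forced_triangle(self):
        g = nx.complete_graph(3)
        h = sample_random_graph(g, np.random.default_rng(0))
        assert edge_key(h) == edge_key(g)

    def test_uniform_over_two_edge_graphs_on_four_nodes(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        g.add_edges_from([(0, 1), (2, 3)])
        rng = np.random.default_rng(123)
        counts = Counter(edge_key(sample_random_graph(g, rng)) for _ in range(15000))
        assert len(counts) == 15
        lo, hi = binom_band(15000, 1 / 15)
        assert all(lo <= c <= hi for c in counts.values())


class TestNodeShuffle:
    def test_adjacency_fixed_and_traits_permuted(self, small_dataset):
        g = small_dataset.graph
        h = sample_node_shuffle(g, np.random.default_rng(5))
        assert edge_key(h) == edge_key(g)
        trees = lambda gr: sorted(
            gr.nodes[v]["tree"].canonical_text for v in gr.nodes if "tree" in gr.nodes[v]
        )
        assert trees(h) == trees(g)
        degs = lambda gr: sorted(d for _, d in gr.degree())
        assert degs(h) == degs(g)

    def test_all_permutations_on_three_path(self):
        g = traited_path(labels=("x", "y", "z"), classes=("a", "a", "a"))
        rng = np.random.default_rng(99)
        counts = Counter()
        for _ in range(6000):
            h = sample_node_shuffle(g, rng)
            counts[tuple(h.nodes[v]["tree"] for v in ("n1", "n2", "n3"))] += 1
        assert len(counts) == 6
        lo, hi = binom_band(6000, 1 / 6)
        assert all(lo <= c <= hi for c in counts.values())


class TestNetworkShuffle:
    def test_degree_map_preserved_every_sample(self, small_dataset):
        g = small_dataset.graph
        rng = np.random.default_rng(2)
        for _ in range(25):
            h = sample_network_shuffle(g, rng)
            assert dict(h.degree()) == dict(g.degree())

    def test_labelled_path_reaches_both_feasible_graphs(self):
        g = traited_path()
        rng = np.random.default_rng(17)
        seen = {edge_key(sample_network_shuffle(g, rng)) for _ in range(200)}
        expected = {
            frozenset({frozenset({"n1", "n2"}), frozenset({"n2", "n3"}), frozenset({"n3", "n4"})}),
            frozenset({frozenset({"n1", "n3"}), frozenset({"n3", "n2"}), frozenset({"n2", "n4"})}),
        }
        assert seen == expected

    def test_triangle_is_frozen(self):
        g = nx.complete_graph(3)
        h = sample_network_shuffle(g, np.random.default_rng(0))
        assert edge_key(h) == edge_key(g)


class TestBioNodeShuffle:
    def test_class_labels_fixed_at_positions(self, small_dataset):
        g = small_dataset.graph
        h = sample_bio_node_shuffle(g, "process", np.random.default_rng(3))
        for v in g.nodes:
            assert (
                h.nodes[v]["classes"]["process"] == g.nodes[v]["classes"]["process"]
            )

    def test_singleton_classes_force_identity(self):
        g = traited_path(classes=("a", "b", "c", "d"))
        h = sample_bio_node_shuffle(g, "process", np.random.default_rng(1))
        assert all(h.nodes[v]["tree"] == g.nodes[v]["tree"] for v in g.nodes)

    def test_single_class_reaches_all_permutations(self):
        g = traited_path(labels=("x", "y", "z"), classes=("a", "a", "a"))
        rng = np.random.default_rng(4)
        seen = set()
        for _ in range(400):
            h = sample_bio_node_shuffle(g, "process", rng)
            seen.add(tuple(h.nodes[v]["tree"] for v in ("n1", "n2", "n3")))
        assert len(seen) == 6

    def test_unknown_characteristic_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            sample_bio_node_shuffle(
                small_dataset.graph, "no_such_thing", np.random.default_rng(0)
            )


class TestBioNetworkShuffle:
    def test_degrees_and_edge_class_multiset_preserved(self, small_dataset):
        g = small_dataset.graph

        def edge_classes(gr):
            return sorted(
                tuple(
                    sorted(
                        (
                            gr.nodes[u]["classes"]["process"],
                            gr.nodes[v]["classes"]["process"],
                        )
                    )
                )
                for u, v in gr.edges()
            )

        rng = np.random.default_rng(8)
        for _ in range(10):
            h = sample_bio_network_shuffle(g, "process", rng)
            assert dict(h.degree()) == dict(g.degree())
            assert edge_classes(h) == edge_classes(g)

    def test_single_class_matches_network_shuffle_support(self):
        g = traited_path(classes=("a", "a", "a", "a"))
        rng = np.random.default_rng(21)
        seen = {
            edge_key(sample_bio_network_shuffle(g, "process", rng)) for _ in range(200)
        }
        assert len(seen) == 2


class TestSpecAndDeterminism:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            EnsembleSpec(model="bogus")
        with pytest.raises(ValueError):
            EnsembleSpec(model="bio_node_shuffle")
        with pytest.raises(ValueError):
            EnsembleSpec(model="node_shuffle", characteristic="process")
        with pytest.raises(ValueError):
            EnsembleSpec(model="node_shuffle", samples=0)

    def test_same_seed_same_sample_sequence(self, small_dataset):
        g = small_dataset.graph
        spec = EnsembleSpec(model="network_shuffle", samples=4, seed=99)
        seq1 = [edge_key(h) for h in sample_ensemble(g, spec)]
        seq2 = [edge_key(h) for h in sample_ensemble(g, spec)]
        assert seq1 == seq2
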