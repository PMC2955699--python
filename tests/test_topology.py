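"""Topology representation, neighbour moves, and the edit distance."""

from collections import deque

import pytest
from hypothesis import given, settings, strategies as st

from coevonet import (
    IncomparableTreesError,
    TreeTopology,
    compare,
    edit_distance,
    enumerate_topologies,
    max_score,
    neighbours,
    parse_topology,
    restrict,
    similarity,
)

ALL5 = enumerate_topologies(5)


def bfs_distances(start: TreeTopology) -> dict:
    """Single-source BFS over the full move graph: the independent oracle
    for the bidirectional search."""
    dist = {start: 0}
    queue = deque([start])
    while queue:
        t = queue.popleft()
        for u in neighbours(t):
            if u not in dist:
                dist[u] = dist[t] + 1
                queue.append(u)
    return dist


class TestParsing:
    @pytest.mark.parametrize(
        "text,canonical",
        [
            ("((2,1),3)", "((1,2),3)"),
            ("((1,2),(5,(3,4)))", "((1,2),((3,4),5))"),
            ("((1,2),(5,(3,4)));", "((1,2),((3,4),5))"),
            ("(B:1.2,(A:0.1,C:0.3):0.9)", "((A,C),B)"),  # branch lengths dropped
            ("(((1,2)),3)", "((1,2),3)"),  # unary node spliced
        ],
    )
    def test_canonicalization(self, text, canonical):
        assert parse_topology(text).canonical_text == canonical

    def test_leaf_set(self):
        t = parse_topology("((1,2),(5,(3,4)))")
        assert t.leaf_set == {"1", "2", "3", "4", "5"}
        assert t.n_leaves == 5

    @pytest.mark.parametrize("bad", ["((1,)2", "", "((1,2),(1,3))", "(1,2))"])
    def test_malformed_or_duplicate_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_topology(bad)

    def test_equality_is_order_invariant(self):
        assert parse_topology("((5,(4,3)),(2,1))") == parse_topology(
            "((1,2),(5,(3,4)))"
        )


class TestRestrict:
    @pytest.mark.parametrize(
        "keep,expected",
        [
            ({"1", "2", "5"}, "((1,2),5)"),
            ({"3", "4", "5"}, "((3,4),5)"),
            ({"1", "3", "4"}, "(1,(3,4))"),
        ],
    )
    def test_prune_and_splice(self, keep, expected):
        t = parse_topology("((1,2),(5,(3,4)))")
        assert restrict(t, keep).canonical_text == expected

    def test_identity_on_full_leaf_set(self):
        t = parse_topology("((1,2),(5,(3,4)))")
        assert restrict(t, t.leaf_set) is t

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            restrict(parse_topology("(1,2,3)"), {"9"})


class TestNeighbours:
    def test_published_example_exact(self):
        t = parse_topology("((1,2),(5,(3,4)))")
        expected = {
            parse_topology("(1,2,(5,(3,4)))"),
            parse_topology("((1,2),(5,3,4))"),
            parse_topology("(5,(1,2),(3,4))"),
        }
        assert neighbours(t) == expected

    def test_three_leaf_star_has_the_three_cherries(self):
        star = parse_topology("(1,2,3)")
        assert neighbours(star) == {
            parse_topology("((1,2),3)"),
            parse_topology("((1,3),2)"),
            parse_topology("((2,3),1)"),
        }

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            neighbours(parse_topology("(1,2)"))

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_move_relation_symmetric_exhaustively(self, n):
        for t in enumerate_topologies(n):
            for u in neighbours(t):
                assert t in neighbours(u), f"{u} -> {t} missing"

    def test_never_contains_self(self):
        for t in enumerate_topologies(4):
            assert t not in neighbours(t)


class TestEditDistance:
    def test_worked_example_is_five(self, worked_example_pair):
        a, b = worked_example_pair
        assert edit_distance(a, b) == 5
        assert edit_distance(b, a) == 5

    def test_identity(self):
        t = parse_topology("((1,2),(5,(3,4)))")
        assert edit_distance(t, t) == 0

    def test_matches_single_source_bfs_oracle_on_random_5_leaf_pairs(self):
        import random

        rnd = random.Random(20240917)
        sources = rnd.sample(ALL5, 8)
        for a in sources:
            oracle = bfs_distances(a)
            for b in rnd.sample(ALL5, 25):
                assert edit_distance(a, b) == oracle[b]

    def test_all_pairs_bounded_by_max_score_n4(self):
        trees = enumerate_topologies(4)
        bound = max_score(4)
        for i, a in enumerate(trees):
            oracle = bfs_distances(a)
            for b in trees[i + 1 :]:
                d = oracle[b]
                assert d <= bound
                assert edit_distance(a, b) == d

    def test_triangle_inequality_sampled(self):
        import random

        rnd = random.Random(7)
        for _ in range(30):
            a, b, c = rnd.sample(ALL5, 3)
            assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)

    def test_incomparable_raises(self):
        with pytest.raises(IncomparableTreesError):
            edit_distance(parse_topology("(1,2,3)"), parse_topology("(4,5,6)"))


class TestMaxScoreAndSimilarity:
    def test_anchor_and_table_values(self):
        assert max_score(3) == 2
        assert max_score(10) == 37

    def test_undefined_below_three(self):
        with pytest.raises(ValueError):
            max_score(2)

    def test_worked_example_similarity(self, worked_example_pair):
        a, b = worked_example_pair
        assert similarity(a, b) == pytest.approx(1 - 5 / 7)

    def test_self_similarity_is_one(self):
        t = parse_topology("((1,2),(5,(3,4)))")
        assert similarity(t, t) == 1.0

    @given(st.sampled_from(ALL5), st.sampled_from(ALL5))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_similarity_in_unit_interval(self, a, b):
        assert 0.0 <= similarity(a, b) <= 1.0


class TestCompare:
    def test_match_after_restriction(self):
        r = compare(parse_topology("((1,2),3)"), parse_topology("((1,2),(3,4))"))
        assert r.status == "match"
        assert r.eta == 0
        assert r.similarity == 1.0
        assert r.shared_species_count == 3

    def test_disjoint_is_incomparable(self):
        r = compare(parse_topology("((1,2),3)"), parse_topology("(4,5,6)"))
        assert r.status == "incomparable"
        assert r.shared_species_count == 0
        assert r.eta is None and r.similarity is None

    def test_worked_example_mismatch(self, worked_example_pair):
        r = compare(*worked_example_pair)
        assert r.status == "mismatch"
        assert r.eta == 5
        assert r.max_score == 7
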