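"""Superbubble detection against hand-built graphs and the definitional oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from bubblechains import (
    BubbleType,
    End,
    NodeNotFoundError,
    Side,
    compact,
    detect_all_bubbles,
    find_superbubble_from,
    is_simple,
    make_diploid_graph,
    make_random_graph,
    oracle_superbubbles,
    DiploidFixtureSpec,
)

from conftest import build_graph


def _keys(bubbles):
    return {(b.source, b.sink, b.interior) for b in bubbles}


class TestFindSuperbubble:
    def test_diamond_from_source(self, diamond):
        sink, interior = find_superbubble_from(diamond, End("s", Side.RIGHT))
        assert sink == End("t", Side.RIGHT)  # exits t rightward, entered at LEFT
        assert interior == {"a", "b"}

    def test_tip_aborts_the_search(self):
        g = build_graph("sab", [("s", "a"), ("s", "b")])  # a, b childless
        assert find_superbubble_from(g, End("s", Side.RIGHT)) is None

    def test_cycle_back_to_source_aborts(self):
        g = build_graph("sab", [("s", "a"), ("s", "b"), ("a", "s"), ("b", "s")])
        assert find_superbubble_from(g, End("s", Side.RIGHT)) is None

    def test_nested_structure_found_from_both_levels(self, fig1_like):
        sink, interior = find_superbubble_from(fig1_like, End("s", Side.RIGHT))
        assert sink.node == "t" and interior == {"a", "b", "c", "d", "e"}
        sink, interior = find_superbubble_from(fig1_like, End("a", Side.RIGHT))
        assert sink.node == "e" and interior == {"c", "d"}

    def test_unknown_source_raises(self, diamond):
        with pytest.raises(NodeNotFoundError):
            find_superbubble_from(diamond, End("nope", Side.LEFT))

    def test_backward_search_finds_the_same_bubble(self, diamond):
        sink, interior = find_superbubble_from(diamond, End("t", Side.LEFT))
        assert sink.node == "s" and interior == {"a", "b"}


class TestClassification:
    def test_diamond_is_simple(self, diamond):
        (b,) = detect_all_bubbles(diamond)
        assert is_simple(diamond, b) and b.btype is BubbleType.SIMPLE

    def test_three_parallel_branches_are_not_simple(self):
        g = build_graph("sabct",
                        [("s", "a"), ("s", "b"), ("s", "c"),
                         ("a", "t"), ("b", "t"), ("c", "t")])
        (b,) = detect_all_bubbles(g)
        assert not is_simple(g, b) and b.btype is BubbleType.SUPER

    def test_interior_with_outside_edge_is_no_superbubble_at_all(self, diamond):
        # an extra edge a -> x breaks reachability matching for (s, t)
        diamond.add_node("x", "ACGT")
        diamond.add_edge(End("a", Side.RIGHT), End("x", Side.LEFT))
        assert find_superbubble_from(diamond, End("s", Side.RIGHT)) is None
        assert _keys(detect_all_bubbles(diamond)) == _keys(oracle_superbubbles(diamond))

    def test_direct_source_sink_edge_with_one_branch_is_insertion(self):
        g = build_graph("sat", [("s", "a"), ("a", "t"), ("s", "t")])
        (b,) = detect_all_bubbles(g)
        assert b.btype is BubbleType.INSERTION
        assert b.interior == frozenset({"a"})


class TestDetectAll:
    def test_edgeless_graph_has_no_bubbles(self):
        assert detect_all_bubbles(build_graph("abc", [])) == []

    def test_nested_bubble_carries_parent_link(self, fig1_like):
        bubbles = detect_all_bubbles(fig1_like)
        by_nodes = {(b.source.node, b.sink.node): b for b in bubbles}
        outer = by_nodes[("s", "t")]
        inner = by_nodes[("a", "e")]
        first = by_nodes[("p", "s")]
        assert inner.parent is outer and inner in outer.nested
        assert outer.parent is None and first.parent is None
        assert inner.btype is BubbleType.SIMPLE and outer.btype is BubbleType.SUPER

    def test_duplicate_discoveries_are_canonicalized(self, diamond):
        bubbles = detect_all_bubbles(diamond)
        assert len(bubbles) == 1
        (b,) = bubbles
        assert b.source <= b.sink
        assert b.source == End("s", Side.RIGHT) and b.sink == End("t", Side.LEFT)

    def test_detection_is_deterministic(self, fig1_like):
        a = [(b.source, b.sink, b.interior) for b in detect_all_bubbles(fig1_like)]
        b = [(x.source, x.sink, x.interior) for x in detect_all_bubbles(fig1_like)]
        assert a == b


class TestOracleEquivalence:
    @pytest.mark.parametrize("edge_prob", [0.1, 0.2, 0.3])
    def test_random_graphs_match_oracle(self, edge_prob):
        for seed in range(60):
            g = make_random_graph(10, edge_prob, seed,
                                  overlap_edges=(seed % 2 == 0),
                                  allow_self_loops=(seed % 7 == 0))
            assert _keys(detect_all_bubbles(g)) == _keys(oracle_superbubbles(g)), seed

    def test_fig1_like_matches_oracle_exactly(self, fig1_like):
        expected = {
            (End("p", Side.RIGHT), End("s", Side.LEFT), frozenset({"q", "r"})),
            (End("s", Side.RIGHT), End("t", Side.LEFT),
             frozenset({"a", "b", "c", "d", "e"})),
            (End("a", Side.RIGHT), End("e", Side.LEFT), frozenset({"c", "d"})),
        }
        assert _keys(oracle_superbubbles(fig1_like)) == expected
        assert _keys(detect_all_bubbles(fig1_like)) == expected

    def test_four_cycle_has_no_bubbles(self):
        g = build_graph("abcd", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        assert oracle_superbubbles(g) == []
        assert detect_all_bubbles(g) == []


class TestStructuralProperties:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_orientation_symmetry(self, seed):
        """Flipping every node's sides maps the bubble set onto itself with
        endpoints flipped."""
        g = make_random_graph(10, 0.25, seed)
        flipped = g.flipped()
        orig = {(b.source, b.sink, b.interior) for b in detect_all_bubbles(g)}
        mirrored = {tuple(sorted((b.source.opposite, b.sink.opposite))) + (b.interior,)
                    for b in detect_all_bubbles(flipped)}
        assert orig == mirrored

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_minimality_and_disjoint_interiors(self, seed):
        g = make_random_graph(12, 0.25, seed)
        bubbles = detect_all_bubbles(g)
        for i, b1 in enumerate(bubbles):
            for b2 in bubbles[i + 1:]:
                if b1.source == b2.source:
                    assert not (b1.interior < b2.interior or b2.interior < b1.interior)
                if b1.parent is not b2 and b2.parent is not b1:
                    if not (b1.node_ids <= b2.interior or b2.node_ids <= b1.interior):
                        assert not (b1.interior & b2.interior)

    def test_detection_agrees_before_and_after_compaction_on_fixture(self):
        spec = DiploidFixtureSpec(seq_length=600, k=15, n_snps=4, seed=11)
        raw, truth = make_diploid_graph(spec, compacted=False)
        compacted = compact(raw)
        assert len(detect_all_bubbles(raw)) == len(detect_all_bubbles(compacted)) \
            == truth.simple_bubbles
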