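"""Bidirected graph model and GFA1 round-tripping."""

import gzip

import pytest
from hypothesis import given, settings, strategies as st

from bubblechains import (
    BidirectedGraph,
    End,
    GFAParseError,
    GraphError,
    NodeNotFoundError,
    Side,
    make_random_graph,
    read_gfa,
    write_gfa,
)

from conftest import build_graph


def _write(tmp_path, text, name="g.gfa"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestSides:
    def test_opposite_is_an_involution(self):
        assert Side.LEFT.opposite is Side.RIGHT
        assert Side.RIGHT.opposite is Side.LEFT
        e = End("x", Side.LEFT)
        assert e.opposite.opposite == e


class TestReadGFA:
    def test_two_segments_one_link(self, tmp_path):
        g = read_gfa(_write(tmp_path, "S\tA\tACGT\nS\tB\tCGTA\nL\tA\t+\tB\t+\t3M\n"))
        assert set(g.nodes) == {"A", "B"}
        assert g.nodes["A"].sequence == "ACGT"
        assert g.adjacency(End("A", Side.RIGHT)) == [(End("B", Side.LEFT), 3)]
        assert g.adjacency(End("B", Side.LEFT)) == [(End("A", Side.RIGHT), 3)]
        g.check_symmetry()

    def test_empty_file_gives_empty_graph(self, tmp_path):
        g = read_gfa(_write(tmp_path, ""))
        assert len(g) == 0

    def test_link_to_undeclared_segment_is_an_error(self, tmp_path):
        with pytest.raises(GFAParseError, match="C"):
            read_gfa(_write(tmp_path, "S\tA\tACGT\nL\tA\t+\tC\t+\t0M\n"))

    def test_links_may_precede_segments(self, tmp_path):
        g = read_gfa(_write(tmp_path, "L\tA\t+\tB\t+\t0M\nS\tA\tAC\nS\tB\tGT\n"))
        assert g.n_edges() == 1

    def test_short_s_line_is_an_error_with_line_number(self, tmp_path):
        with pytest.raises(GFAParseError, match="line 2"):
            read_gfa(_write(tmp_path, "S\tA\tACGT\nS\tB\n"))

    @pytest.mark.parametrize("cigar", ["3M1I", "xyz", "M", "3"])
    def test_non_match_cigar_is_an_error(self, tmp_path, cigar):
        with pytest.raises(GFAParseError, match="CIGAR"):
            read_gfa(_write(tmp_path, f"S\tA\tACGT\nS\tB\tACGT\nL\tA\t+\tB\t+\t{cigar}\n"))

    def test_star_cigar_means_blunt(self, tmp_path):
        g = read_gfa(_write(tmp_path, "S\tA\tACGT\nS\tB\tACGT\nL\tA\t+\tB\t+\t*\n"))
        assert next(iter(g.edges()))[2] == 0

    def test_orientation_mapping_reverse(self, tmp_path):
        # "L A + B - 0M": leaves A.RIGHT, enters B.RIGHT
        g = read_gfa(_write(tmp_path, "S\tA\tACGT\nS\tB\tACGT\nL\tA\t+\tB\t-\t0M\n"))
        a_right = End("A", Side.RIGHT)
        assert g.neighbors(a_right) == [End("B", Side.RIGHT)]
        # traversal continues out of B's opposite (LEFT) side
        assert g.children(a_right) == [End("B", Side.LEFT)]

    def test_duplicate_and_reverse_duplicate_links_are_merged(self, tmp_path):
        text = ("S\tA\tACGT\nS\tB\tACGT\n"
                "L\tA\t+\tB\t+\t0M\nL\tA\t+\tB\t+\t0M\nL\tB\t-\tA\t-\t0M\n")
        g = read_gfa(_write(tmp_path, text))
        assert g.n_edges() == 1

    def test_length_only_mode_uses_ln_tag(self, tmp_path):
        g = read_gfa(_write(tmp_path, "S\tA\t*\tLN:i:7\n"), keep_sequences=False)
        assert g.nodes["A"].length == 7 and g.nodes["A"].sequence == ""

    def test_star_sequence_without_ln_tag_is_an_error(self, tmp_path):
        with pytest.raises(GFAParseError, match="LN"):
            read_gfa(_write(tmp_path, "S\tA\t*\n"))

    def test_keep_sequences_off_drops_sequence_keeps_length(self, tmp_path):
        g = read_gfa(_write(tmp_path, "S\tA\tACGTACGT\n"), keep_sequences=False)
        assert g.nodes["A"].sequence == "" and g.nodes["A"].length == 8

    def test_gzip_input(self, tmp_path):
        p = tmp_path / "g.gfa.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("S\tA\tACGT\n")
        assert set(read_gfa(p).nodes) == {"A"}

    def test_unknown_record_types_are_ignored(self, tmp_path):
        g = read_gfa(_write(tmp_path, "H\tVN:Z:1.0\nS\tA\tAC\nP\tp1\tA+\t*\n"))
        assert set(g.nodes) == {"A"}


class TestWriteGFA:
    def test_round_trip_of_simple_pair(self, tmp_path):
        g = build_graph({"A": "ACGT", "B": "CGTA"},
                        [("A", Side.RIGHT, "B", Side.LEFT, 3)])
        p = tmp_path / "out.gfa"
        write_gfa(g, p)
        h = read_gfa(p)
        assert sorted(h.edges()) == sorted(g.edges())
        assert h.nodes["A"].sequence == "ACGT"

    def test_tags_written_verbatim(self, tmp_path):
        g = build_graph({"A": "ACGT"}, [])
        p = tmp_path / "out.gfa"
        write_gfa(g, p, tags={"A": ["BC:i:7"]})
        s_line = [l for l in p.read_text().splitlines() if l.startswith("S")][0]
        assert "BC:i:7" in s_line.split("\t")

    def test_each_edge_written_once(self, tmp_path):
        g = build_graph("ab", [("a", "b"), ("b", Side.RIGHT, "a", Side.LEFT, 0)])
        p = tmp_path / "out.gfa"
        write_gfa(g, p)
        l_lines = [l for l in p.read_text().splitlines() if l.startswith("L")]
        assert len(l_lines) == g.n_edges() == 2

    def test_node_without_sequence_or_length_is_an_error(self, tmp_path):
        g = BidirectedGraph()
        g.add_node("A")
        with pytest.raises(GraphError):
            write_gfa(g, tmp_path / "out.gfa")


class TestAdjacency:
    def test_neighbors_of_branching_end(self, diamond):
        assert set(diamond.neighbors(End("s", Side.RIGHT))) == {
            End("a", Side.LEFT), End("b", Side.LEFT)}

    def test_isolated_end_has_no_neighbors(self):
        g = build_graph("x", [])
        assert g.neighbors(End("x", Side.LEFT)) == []

    def test_unknown_node_raises(self, diamond):
        with pytest.raises(NodeNotFoundError):
            diamond.neighbors(End("zzz", Side.LEFT))

    def test_parents_invert_children(self, diamond):
        s_right = End("s", Side.RIGHT)
        for child in diamond.children(s_right):
            assert s_right in diamond.parents(child)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(seed=st.integers(0, 10**6), overlaps=st.booleans(), loops=st.booleans())
def test_gfa_round_trip_is_isomorphic(tmp_path_factory, seed, overlaps, loops):
    """write -> read preserves node ids, sequences and the symmetric
    adjacency structure with overlaps, for arbitrary random graphs."""
    g = make_random_graph(10, 0.25, seed, overlap_edges=overlaps,
                          allow_self_loops=loops)
    p = tmp_path_factory.mktemp("rt") / "g.gfa"
    write_gfa(g, p)
    h = read_gfa(p)
    assert set(h.nodes) == set(g.nodes)
    assert all(h.nodes[n].sequence == g.nodes[n].sequence for n in g.nodes)
    assert sorted(h.edges()) == sorted(g.edges())
    h.check_symmetry()
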