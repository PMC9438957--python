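import logging

import pytest

from bubblechains import BidirectedGraph, End, Side


def build_graph(nodes, edges, k=None):
    """Small-graph builder for tests.

    ``nodes``: mapping id -> sequence (or iterable of ids, sequence "ACGTA").
    ``edges``: iterables (u, v) for a blunt u.RIGHT--v.LEFT edge, or
    (u, u_side, v, v_side, overlap) in full form with Side values.
    """
    g = BidirectedGraph(k=k)
    if isinstance(nodes, dict):
        for nid, seq in nodes.items():
            g.add_node(nid, seq)
    else:
        for nid in nodes:
            g.add_node(nid, "ACGTA")
    for e in edges:
        if len(e) == 2:
            u, v = e
            g.add_edge(End(u, Side.RIGHT), End(v, Side.LEFT), 0)
        else:
            u, su, v, sv, ov = e
            g.add_edge(End(u, su), End(v, sv), ov)
    return g


@pytest.fixture
def diamond():
    """s -> {a, b} -> t: the smallest simple bubble."""
    return build_graph("sabt", [("s", "a"), ("s", "b"), ("a", "t"), ("b", "t")])


@pytest.fixture
def fig1_like():
    """A chain of one simple bubble and one superbubble with a simple bubble
    nested inside: p->{q,r}->s, then s->{a,b}, b->t, a->{c,d}, c->e, d->e, e->t."""
    return build_graph(
        "pqrsabcdet",
        [("p", "q"), ("p", "r"), ("q", "s"), ("r", "s"),
         ("s", "a"), ("s", "b"), ("b", "t"),
         ("a", "c"), ("a", "d"), ("c", "e"), ("d", "e"), ("e", "t")],
    )


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # parser warnings (duplicate/self links) are expected in several tests
    logging.getLogger("bubblechains.gfa").setLevel(logging.ERROR)
    yield
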