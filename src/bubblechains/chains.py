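"""Bubble chains and the detection report.

A *bubble chain* is a maximal linear run of top-level bubbles in which the
sink node of one bubble is the source node of the next.  An endpoint node
where three or more bubbles meet breaks the chain (chains are linear, never
branching), and nested bubbles travel inside their enclosing superbubble
rather than as chain members of their own.

Chain *size* is reported in two units, since either can drive the choice of
k when building de Bruijn graphs: the number of bubbles, and a base-pair
span defined as the longest source-to-sink walk through each bubble (edge
overlaps subtracted) with shared endpoint nodes counted once.
"""

from __future__ import annotations

import json
from collections import defaultdict, deque
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

from .bubbles import Bubble, BubbleType
from .graph import BidirectedGraph, End

__all__ = ["BubbleChain", "DetectionReport", "build_chains", "build_report"]


@dataclass
class BubbleChain:
    """An ordered run of bubbles with coinciding sinks/sources."""

    chain_id: int
    bubbles: list[Bubble]
    ends: tuple[str, str]
    length_in_bases: int = 0

    @property
    def length_in_bubbles(self) -> int:
        return len(self.bubbles)

    def node_ids(self) -> set[str]:
        out: set[str] = set()
        for b in self.bubbles:
            out |= b.node_ids
        return out


def _longest_walk(graph: BidirectedGraph, bubble: Bubble) -> int:
    """Base-pair length of the longest source-to-sink walk through a bubble
    (spelled length: node lengths minus edge overlaps), endpoints included.

    The bubble subgraph is acyclic in its traversal orientation, so a
    memoised depth-first recursion terminates.
    """
    inside = bubble.node_ids
    target = bubble.sink.opposite  # directed node exiting the sink outward

    @lru_cache(maxsize=None)
    def tail(v: End) -> int:
        # max spelled bases contributed beyond v's node, walking to the sink
        if v == target:
            return 0
        best = None
        for (e, overlap) in graph.adjacency(v):
            u = e.opposite  # next directed node
            if e.node not in inside:
                continue
            t = tail(u)
            if t is None:
                continue
            gain = graph.node(e.node).length - overlap + t
            if best is None or gain > best:
                best = gain
        return best

    total = tail(bubble.source)
    src_len = graph.node(bubble.source.node).length
    return src_len + (total or 0)


def build_chains(graph: BidirectedGraph, bubbles: Iterable[Bubble]) -> list[BubbleChain]:
    """Partition the top-level bubbles into maximal linear chains.

    Two bubbles are linked when they are the only two bubbles meeting at a
    shared endpoint node.  Isolated bubbles form chains of length one.  Each
    chain is ordered starting from its lexicographically smaller outer
    endpoint, and chains are numbered 1..n after sorting by starting end.
    """
    top = sorted((b for b in bubbles if b.parent is None),
                 key=lambda b: (b.source, b.sink))
    by_node: dict[str, list[Bubble]] = defaultdict(list)
    for b in top:
        by_node[b.source.node].append(b)
        by_node[b.sink.node].append(b)

    assigned: set[Bubble] = set()
    raw: list[tuple[list[Bubble], tuple[str, str]]] = []
    for seed in top:
        if seed in assigned:
            continue
        members: deque[Bubble] = deque([seed])
        assigned.add(seed)
        left, right = seed.source.node, seed.sink.node

        def _grow(endpoint: str) -> tuple[list[Bubble], str]:
            grown: list[Bubble] = []
            while len(by_node[endpoint]) == 2:
                nxt = [x for x in by_node[endpoint] if x not in assigned]
                if not nxt:
                    break  # chain closed into a cycle or partner consumed
                bub = nxt[0]
                assigned.add(bub)
                grown.append(bub)
                endpoint = (bub.sink.node if bub.source.node == endpoint
                            else bub.source.node)
            return grown, endpoint

        grown_r, right = _grow(right)
        members.extend(grown_r)
        grown_l, left = _grow(left)
        members.extendleft(grown_l)

        ordered = list(members)
        if right < left:
            ordered.reverse()
            left, right = right, left
        raw.append((ordered, (left, right)))

    raw.sort(key=lambda item: (item[1], len(item[0])))
    chains = []
    for i, (ordered, ends) in enumerate(raw, start=1):
        walks = sum(_longest_walk(graph, b) for b in ordered)
        shared = sum(_shared_endpoint_length(graph, a, b)
                     for a, b in zip(ordered, ordered[1:]))
        chains.append(BubbleChain(i, ordered, ends, walks - shared))
    return chains


def _shared_endpoint_length(graph: BidirectedGraph, a: Bubble, b: Bubble) -> int:
    shared = ({a.source.node, a.sink.node} & {b.source.node, b.sink.node})
    return sum(graph.node(n).length for n in shared)


@dataclass
class DetectionReport:
    """JSON-serialisable summary of a detection run."""

    chains: list[BubbleChain]
    counts: dict
    node_chain_ids: dict[str, int] = field(default_factory=dict)

    def gfa_tags(self) -> dict[str, list[str]]:
        """Per-node ``BC:i:<chain id>`` tags (0 = in no chain)."""
        return {n: [f"BC:i:{cid}"] for n, cid in sorted(self.node_chain_ids.items())}

    def to_dict(self) -> dict:
        return {
            "chains": [_chain_dict(c) for c in self.chains],
            "counts": dict(self.counts),
        }

    def to_json(self) -> str:
        """Deterministic JSON text (fixed key order, no timestamps)."""
        return json.dumps(self.to_dict(), indent=2)


def _bubble_dict(b: Bubble) -> dict:
    return {
        "source": b.source.node,
        "sink": b.sink.node,
        "type": b.btype.value,
        "interior": sorted(b.interior),
        "nested": [_bubble_dict(n) for n in b.nested],
    }


def _chain_dict(c: BubbleChain) -> dict:
    return {
        "id": c.chain_id,
        "ends": list(c.ends),
        "length_in_bubbles": c.length_in_bubbles,
        "length_in_bases": c.length_in_bases,
        "bubbles": [_bubble_dict(b) for b in c.bubbles],
    }


def build_report(graph: BidirectedGraph, chains: list[BubbleChain],
                 bubbles: Optional[Iterable[Bubble]] = None) -> DetectionReport:
    """Assemble the detection report for a graph.

    ``bubbles`` is the full bubble list (including nested ones); when
    omitted it is reconstructed from the chains.  Counts cover every bubble:
    nested simple bubbles are included in ``simple_bubbles`` and broken out
    again under ``nested_simple_bubbles``.
    """
    if bubbles is None:
        collected: list[Bubble] = []

        def _walk(b: Bubble) -> None:
            collected.append(b)
            for n in b.nested:
                _walk(n)

        for c in chains:
            for b in c.bubbles:
                _walk(b)
        bubbles = collected
    bubbles = list(bubbles)

    counts = {
        "simple_bubbles": sum(b.btype is BubbleType.SIMPLE for b in bubbles),
        "superbubbles": sum(b.btype is BubbleType.SUPER for b in bubbles),
        "insertion_bubbles": sum(b.btype is BubbleType.INSERTION for b in bubbles),
        "nested_simple_bubbles": sum(
            b.btype is BubbleType.SIMPLE and b.parent is not None for b in bubbles),
        "chains": len(chains),
        "longest_chain_in_bubbles": max((c.length_in_bubbles for c in chains), default=0),
        "longest_chain_in_bases": max((c.length_in_bases for c in chains), default=0),
    }
    node_chain_ids = {nid: 0 for nid in graph.nodes}
    for c in chains:
        for nid in c.node_ids():
            node_chain_ids[nid] = c.chain_id
    return DetectionReport(chains, counts, node_chain_ids)
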