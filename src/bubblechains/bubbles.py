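"""Superbubble, simple-bubble and nested-bubble detection.

A *superbubble* between a source node ``s`` and a sink node ``t`` is a
minimal subgraph that is directed and acyclic under the orientation induced
by entering it from ``s``, in which the set of nodes reachable from ``s``
equals the set of nodes from which ``t`` can be reached, and no interior
node forms such a pair with ``s`` or ``t`` itself.  A *simple bubble* is the
special case with exactly two disjoint interior paths — after compaction,
exactly two interior nodes, each adjacent only to the source and sink ends.
An *insertion bubble* has a single interior branch in parallel with a direct
source-sink edge (a length-polymorphic site); it is reported as its own
category, not as a simple bubble.

Detection runs the classic frontier search from every oriented end of every
node: maintain ``seen`` (reached) and ``visited`` (processed) directed
nodes, repeatedly pop a node all of whose parents are visited, and succeed
when the frontier collapses to a single node with nothing else pending.  On
a bidirected graph, directed nodes are (node, orientation) pairs; a search
that reaches some node in both orientations is aborted, since the doubled
directed subgraph could not be acyclic.  Each bubble is found once from its
source going forward and once from its sink going backward; the two are
merged into one canonical object whose endpoints are the two bubble-facing
ends ordered lexicographically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .graph import BidirectedGraph, End, Side

__all__ = [
    "Bubble",
    "BubbleType",
    "find_superbubble_from",
    "detect_all_bubbles",
    "is_simple",
]


class BubbleType(str, enum.Enum):
    SIMPLE = "simple"
    SUPER = "super"
    INSERTION = "insertion"


@dataclass(eq=False)
class Bubble:
    """A detected (super)bubble in canonical form.

    ``source`` and ``sink`` are the two endpoint ends *facing into* the
    bubble, ordered so that ``source <= sink``; ``interior`` holds the node
    ids strictly inside.  ``parent`` links a nested bubble to the smallest
    enclosing one; ``nested`` lists the immediate children.
    """

    source: End
    sink: End
    interior: frozenset[str]
    btype: BubbleType = BubbleType.SUPER
    parent: Optional["Bubble"] = None
    nested: list["Bubble"] = field(default_factory=list)

    @property
    def key(self) -> tuple[End, End, frozenset[str]]:
        return (self.source, self.sink, self.interior)

    @property
    def is_simple(self) -> bool:
        return self.btype is BubbleType.SIMPLE

    @property
    def node_ids(self) -> frozenset[str]:
        """All node ids of the bubble, endpoints included."""
        return self.interior | {self.source.node, self.sink.node}

    def __eq__(self, other) -> bool:
        return isinstance(other, Bubble) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"Bubble({self.source!r}->{self.sink!r}, "
                f"interior={sorted(self.interior)}, {self.btype.value})")


def find_superbubble_from(graph: BidirectedGraph, source: End):
    """Search for the minimal superbubble headed by the directed node that
    exits ``source.node`` at ``source.side``.

    Returns ``(sink, interior)`` on success — ``sink`` being the directed
    node (exit-end convention) at which the walk leaves the bubble and
    ``interior`` the set of interior node ids — or ``None`` when no
    superbubble starts here (a tip is reached, a cycle returns to the
    source, some node is reached in both orientations, or the frontier never
    collapses).
    """
    graph.node(source.node)  # raises NodeNotFoundError for unknown ids
    seen: set[End] = {source}
    visited: set[End] = set()
    on_stack: set[End] = {source}
    stack: list[End] = [source]

    while stack:
        v = stack.pop()
        on_stack.discard(v)
        visited.add(v)
        seen.discard(v)

        children = sorted(set(graph.children(v)))
        if not children:
            return None  # tip: dead end inside the candidate bubble
        for u in children:
            if u == source:
                return None  # cycle back to the source
            if u.opposite in seen or u.opposite in visited:
                return None  # node reached in both orientations
            if u in visited:
                return None  # re-entering a processed node: oriented cycle
            seen.add(u)
            if u not in on_stack and all(p in visited for p in graph.parents(u)):
                stack.append(u)
                on_stack.add(u)

        if len(stack) == 1 and len(seen) == 1:
            t = stack[0]
            if source in graph.children(t):
                return None  # sink has an edge back to the source
            interior = {e.node for e in visited} - {source.node}
            if not interior:
                return None  # adjacent pair, not a bubble
            return t, frozenset(interior)
    return None


def _interior_is_simple_branch(graph: BidirectedGraph, node_id: str,
                               src: End, snk: End) -> bool:
    """True when ``node_id`` has exactly one edge per side, one to the source
    end and one to the sink end."""
    node = graph.node(node_id)
    if len(node.adj[0]) != 1 or len(node.adj[1]) != 1:
        return False
    neighbors = {node.adj[0][0][0], node.adj[1][0][0]}
    return neighbors == {src, snk}


def classify(graph: BidirectedGraph, bubble: Bubble) -> BubbleType:
    """Classify a bubble as simple, insertion or (general) super.

    Simplicity is meaningful on a compacted graph, where each branch of a
    two-path bubble is a single node.
    """
    src, snk = bubble.source, bubble.sink
    direct = snk in graph.neighbors(src)
    if len(bubble.interior) == 1 and direct:
        return BubbleType.INSERTION
    if (len(bubble.interior) == 2 and not direct
            and all(_interior_is_simple_branch(graph, n, src, snk)
                    for n in bubble.interior)):
        return BubbleType.SIMPLE
    return BubbleType.SUPER


def is_simple(graph: BidirectedGraph, bubble: Bubble) -> bool:
    """Whether ``bubble`` has exactly two disjoint interior paths (on a
    compacted graph: two interior nodes wired only to source and sink)."""
    return classify(graph, bubble) is BubbleType.SIMPLE


def _canonical(source: End, sink_directed: End, interior: frozenset[str]) -> tuple[End, End]:
    """Canonical endpoint pair: both ends face into the bubble; the search
    exits the sink node at ``sink_directed.side``, so the bubble-facing sink
    end is its opposite."""
    a, b = sorted((source, sink_directed.opposite))
    return a, b


def detect_all_bubbles(graph: BidirectedGraph) -> list[Bubble]:
    """Enumerate every superbubble in the graph, classified and with nesting
    links resolved.

    The frontier search is started from both ends of every node (skipping
    ends with fewer than two distinct children, which cannot head a minimal
    superbubble); the two discoveries of each bubble are merged into one
    canonical :class:`Bubble`.  A bubble whose node set lies inside another
    bubble's interior is nested there; ``parent`` points to the smallest such
    enclosing bubble.  Processing order is sorted throughout, so the result
    is deterministic and returned sorted by endpoints.
    """
    found: dict[tuple[End, End], Bubble] = {}
    for node_id in sorted(graph.nodes):
        for side in (Side.LEFT, Side.RIGHT):
            src = End(node_id, side)
            if len(set(graph.children(src))) < 2:
                continue
            result = find_superbubble_from(graph, src)
            if result is None:
                continue
            sink, interior = result
            a, b = _canonical(src, sink, interior)
            prev = found.get((a, b))
            if prev is not None:
                assert prev.interior == interior, "direction-dependent interior"
                continue
            found[(a, b)] = Bubble(a, b, interior)

    bubbles = sorted(found.values(), key=lambda b: (b.source, b.sink))
    for b in bubbles:
        b.btype = classify(graph, b)

    # nesting: smallest enclosing interior wins
    by_size = sorted(bubbles, key=lambda b: len(b.interior))
    for i, inner in enumerate(by_size):
        best = None
        for outer in by_size[i + 1:]:
            if len(outer.interior) <= len(inner.interior):
                continue
            if inner.node_ids <= outer.interior:
                if best is None or len(outer.interior) < len(best.interior):
                    best = outer
        if best is not None:
            inner.parent = best
            best.nested.append(inner)
    for b in bubbles:
        b.nested.sort(key=lambda x: (x.source, x.sink))
    return bubbles
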