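"""Bidirected sequence-graph data model.

A bidirected graph represents DNA segments as nodes with two *sides*
(``LEFT`` and ``RIGHT``).  An edge joins a specific side of one node to a
specific side of another, which encodes the relative orientation of the two
sequences: walking "forward" through a node means entering at one side and
leaving at the other.  This is the native model of assembly and pangenome
graphs exchanged in GFA, where a segment used in reverse orientation
contributes its reverse complement.

Traversal convention
--------------------
A *directed node* (a node visited in a particular orientation) is represented
by the :class:`End` it will exit from.  Its children are obtained by
following the edges attached to that exit end; each edge enters a neighbour
at some side, and the walk continues out of the *opposite* side of that
neighbour.  :meth:`BidirectedGraph.children` and
:meth:`BidirectedGraph.parents` implement exactly this, so the doubled
directed graph used by the superbubble machinery never needs to be
materialised.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional

from .errors import GraphError, NodeNotFoundError

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Side(enum.IntEnum):
    """One of the two sides of a node in a bidirected graph."""

    LEFT = 0
    RIGHT = 1

    @property
    def opposite(self) -> "Side":
        return Side(1 - self.value)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class End(NamedTuple):
    """A (node id, side) pair: the unit of adjacency and traversal."""

    node: str
    side: Side

    @property
    def opposite(self) -> "End":
        """Same node, other side."""
        return End(self.node, self.side.opposite)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.node}.{self.side.name[0]}"


@dataclass
class Node:
    """A segment: id, sequence (possibly empty in length-only mode) and the
    per-side adjacency lists of ``(End, overlap)`` pairs."""

    node_id: str
    sequence: str = ""
    length: int = 0
    adj: tuple[list, list] = field(default_factory=lambda: ([], []))

    def __post_init__(self) -> None:
        if self.sequence:
            self.length = len(self.sequence)

    def degree(self) -> int:
        return len(self.adj[0]) + len(self.adj[1])


class BidirectedGraph:
    """Mutable bidirected graph with symmetric edge storage.

    Every edge is recorded in the adjacency list of both incident ends, so it
    is discoverable from either node; :meth:`add_edge` maintains this
    invariant and silently refuses duplicates (returning ``False``).
    """

    def __init__(self, k: Optional[int] = None):
        self.nodes: dict[str, Node] = {}
        self.k = k

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    # -- construction -------------------------------------------------------
    def add_node(self, node_id: str, sequence: str = "", length: Optional[int] = None) -> Node:
        if node_id in self.nodes:
            raise GraphError(f"duplicate node id {node_id!r}")
        node = Node(node_id, sequence, length if length is not None else 0)
        self.nodes[node_id] = node
        return node

    def add_edge(self, a: End, b: End, overlap: int = 0) -> bool:
        """Insert the undirected (side-to-side) edge a<->b.

        Returns False (and changes nothing) if an edge between the same pair
        of ends already exists, whatever its overlap.
        """
        if overlap < 0:
            raise GraphError("negative overlap")
        na, nb = self.node(a.node), self.node(b.node)
        if any(e == b for e, _ in na.adj[a.side]):
            return False
        na.adj[a.side].append((b, overlap))
        if a != b:  # a self-edge on one single end is stored once
            nb.adj[b.side].append((a, overlap))
        return True

    # -- queries ------------------------------------------------------------
    def node(self, node_id: str) -> Node:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise NodeNotFoundError(node_id) from None

    def adjacency(self, end: End) -> list[tuple[End, int]]:
        return self.node(end.node).adj[end.side]

    def neighbors(self, end: End) -> list[End]:
        """Ends adjacent to ``end``.  Traversal continues out of the opposite
        side of each neighbour reached."""
        return [e for e, _ in self.adjacency(end)]

    def degree(self, end: End) -> int:
        return len(self.adjacency(end))

    def node_neighbors(self, node_id: str) -> set[str]:
        """Node ids adjacent to either side of ``node_id`` (undirected view)."""
        node = self.node(node_id)
        return {e.node for side in (Side.LEFT, Side.RIGHT) for e, _ in node.adj[side]}

    def children(self, v: End) -> list[End]:
        """Successors of the directed node that exits ``v.node`` at ``v.side``,
        themselves given as directed nodes (exit ends)."""
        return [e.opposite for e in self.neighbors(v)]

    def parents(self, v: End) -> list[End]:
        """Predecessor directed nodes of the directed node ``v`` (exit-end
        convention): the ends adjacent to v's entry side."""
        return self.neighbors(v.opposite)

    def edges(self) -> Iterator[tuple[End, End, int]]:
        """Iterate every undirected edge exactly once (canonical: reported
        from its lexicographically smaller end)."""
        for node_id in self.nodes:
            node = self.nodes[node_id]
            for side in (Side.LEFT, Side.RIGHT):
                a = End(node_id, side)
                for b, overlap in node.adj[side]:
                    if a <= b:
                        yield a, b, overlap

    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    # -- derived graphs -----------------------------------------------------
    def subgraph(self, node_ids: Iterable[str]) -> "BidirectedGraph":
        """Induced subgraph on ``node_ids`` (nodes copied, edges kept when
        both endpoints are inside)."""
        keep = set(node_ids)
        sub = BidirectedGraph(k=self.k)
        for nid in sorted(keep):
            src = self.node(nid)
            sub.add_node(nid, src.sequence, src.length)
        for a, b, overlap in self.edges():
            if a.node in keep and b.node in keep:
                sub.add_edge(a, b, overlap)
        return sub

    def flipped(self) -> "BidirectedGraph":
        """Copy of the graph with LEFT and RIGHT exchanged on every node."""
        out = BidirectedGraph(k=self.k)
        for nid, node in self.nodes.items():
            out.add_node(nid, node.sequence, node.length)
        for a, b, overlap in self.edges():
            out.add_edge(a.opposite, b.opposite, overlap)
        return out

    # -- invariants ---------------------------------------------------------
    def check_symmetry(self) -> None:
        """Raise GraphError unless adjacency is stored symmetrically and all
        references resolve; used by tests and after mutating operations."""
        for nid, node in self.nodes.items():
            for side in (Side.LEFT, Side.RIGHT):
                here = End(nid, side)
                seen: set[End] = set()
                for other, overlap in node.adj[side]:
                    if other.node not in self.nodes:
                        raise GraphError(f"edge {here}->{other} references unknown node")
                    if other in seen:
                        raise GraphError(f"duplicate adjacency {here}->{other}")
                    seen.add(other)
                    back = self.nodes[other.node].adj[other.side]
                    if not any(e == here and ov == overlap for e, ov in back):
                        raise GraphError(f"asymmetric edge {here}->{other}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BidirectedGraph({len(self.nodes)} nodes, {self.n_edges()} edges)"
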