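"""Utility operations on bidirected graphs.

* :func:`compact` merges maximal linear stretches (unitigs) into single
  nodes, trimming edge overlaps, exactly as one compacts a de Bruijn graph.
* :func:`biggest_component` extracts the connected component with the most
  nodes.
* :func:`extract_neighborhood` cuts out a breadth-first neighbourhood of a
  given node count around a start node, for visualisation.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Optional

from .errors import CompactionError, GraphError
from .graph import BidirectedGraph, End, Side, reverse_complement

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# linear-path compaction
# ---------------------------------------------------------------------------

def _merge_partner(graph: BidirectedGraph, end: End) -> Optional[tuple[End, int]]:
    """The end that ``end`` can be merged through, if any.

    Two nodes can be merged across an edge only when that edge is the sole
    edge on both of its incident ends (each connecting side has exactly one
    edge) and the edge is not a self-link.  A node with two edges attached to
    the same side is a junction and is never merged through.
    """
    adj = graph.adjacency(end)
    if len(adj) != 1:
        return None
    other, overlap = adj[0]
    if other.node == end.node:
        return None
    if len(graph.adjacency(other)) != 1:
        return None
    return other, overlap


def _walk_linear_path(graph: BidirectedGraph, start: str):
    """Maximal linear path containing ``start``.

    Returns ``(members, overlaps, circular, closing_overlap)`` where
    ``members`` is a list of ``(node_id, forward)`` oriented nodes and
    ``overlaps[i]`` is the overlap between members i and i+1.  A circular
    path (every node 1-in/1-out around a cycle) is closed by
    ``closing_overlap`` instead of having outer ends.
    """
    members: deque[tuple[str, bool]] = deque([(start, True)])
    overlaps: deque[int] = deque()
    in_path = {start}

    # grow to the right of the (arbitrary) start orientation
    circular = False
    closing_overlap = 0
    while True:
        nid, fwd = members[-1]
        exit_end = End(nid, Side.RIGHT if fwd else Side.LEFT)
        step = _merge_partner(graph, exit_end)
        if step is None:
            break
        other, overlap = step
        if other.node in in_path:
            # with one edge per connecting side the only possible revisit is
            # a consistent closure onto the first member
            first_id, first_fwd = members[0]
            entry = End(first_id, Side.LEFT if first_fwd else Side.RIGHT)
            assert other == entry, "inconsistent path closure"
            circular = True
            closing_overlap = overlap
            break
        members.append((other.node, other.side is Side.LEFT))
        overlaps.append(overlap)
        in_path.add(other.node)

    if not circular:
        while True:
            nid, fwd = members[0]
            entry_end = End(nid, Side.LEFT if fwd else Side.RIGHT)
            step = _merge_partner(graph, entry_end)
            if step is None:
                break
            other, overlap = step
            if other.node in in_path:
                break  # closure already handled from the right in circular case
            # the prepended node exits toward us at other.side
            members.appendleft((other.node, other.side is Side.RIGHT))
            overlaps.appendleft(overlap)
            in_path.add(other.node)

    return list(members), list(overlaps), circular, closing_overlap


def _normalize_path(members, overlaps, circular):
    """Deterministic canonical direction for a linear path.

    Circular paths are already canonical: nodes are visited in sorted id
    order, so the walk necessarily started from the smallest id in the
    cycle, oriented forward.
    """
    if circular:
        assert members[0][1], "circular walk must start forward"
        return members, overlaps
    if len(members) > 1 and members[-1][0] < members[0][0]:
        members = [(n, not f) for n, f in reversed(members)]
        overlaps = list(reversed(overlaps))
    return members, overlaps


def _spell(graph: BidirectedGraph, members, overlaps):
    """Concatenate a path's sequences (or lengths), trimming overlaps."""
    nodes = [graph.node(nid) for nid, _ in members]
    seq_mode = all(n.sequence for n in nodes)
    first = nodes[0]
    seq = (first.sequence if members[0][1] else reverse_complement(first.sequence)) \
        if seq_mode else ""
    length = first.length
    for (nid, fwd), node, overlap in zip(members[1:], nodes[1:], overlaps):
        if overlap >= node.length:
            raise CompactionError(
                f"overlap {overlap} >= length {node.length} of node {nid!r} during merge"
            )
        if seq_mode:
            oriented = node.sequence if fwd else reverse_complement(node.sequence)
            seq += oriented[overlap:]
        length += node.length - overlap
    return seq, length


def compact(graph: BidirectedGraph) -> BidirectedGraph:
    """Merge every maximal linear stretch of nodes into a single node.

    The merged node's sequence is the concatenation of the members' oriented
    sequences with each edge's overlap removed from the successor's prefix
    (lengths are summed minus overlaps when sequences are absent); its id is
    the members' ids joined with ``_`` in path order.  External edges are
    reattached to the merged node's outer ends.  Circular linear paths
    compact to a single node carrying a self-loop.  The result has no
    remaining mergeable pair, making the operation idempotent.
    """
    paths = []
    assigned: set[str] = set()
    for nid in sorted(graph.nodes):
        if nid in assigned:
            continue
        members, overlaps, circular, closing = _walk_linear_path(graph, nid)
        members, overlaps = _normalize_path(members, overlaps, circular)
        assigned.update(n for n, _ in members)
        paths.append((members, overlaps, circular, closing))

    out = BidirectedGraph(k=graph.k)
    end_map: dict[End, End] = {}
    for members, overlaps, circular, closing in paths:
        if len(members) == 1 and not circular:
            nid = members[0][0]
            node = graph.node(nid)
            out.add_node(nid, node.sequence, node.length)
            end_map[End(nid, Side.LEFT)] = End(nid, Side.LEFT)
            end_map[End(nid, Side.RIGHT)] = End(nid, Side.RIGHT)
            continue
        merged_id = "_".join(n for n, _ in members)
        while merged_id in out:  # defensive: user ids may contain underscores
            merged_id += "+"
        seq, length = _spell(graph, members, overlaps)
        out.add_node(merged_id, seq, length)
        if circular:
            out.add_edge(End(merged_id, Side.RIGHT), End(merged_id, Side.LEFT), closing)
            continue
        first_id, first_fwd = members[0]
        last_id, last_fwd = members[-1]
        end_map[End(first_id, Side.LEFT if first_fwd else Side.RIGHT)] = End(merged_id, Side.LEFT)
        end_map[End(last_id, Side.RIGHT if last_fwd else Side.LEFT)] = End(merged_id, Side.RIGHT)

    for a, b, overlap in graph.edges():
        ma, mb = end_map.get(a), end_map.get(b)
        if ma is None and mb is None:
            continue  # path-internal edge, consumed by a merge
        assert ma is not None and mb is not None, "edge with one internal end"
        out.add_edge(ma, mb, overlap)
    return out


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------

def connected_components(graph: BidirectedGraph) -> list[set[str]]:
    """Connected components of the underlying undirected node graph (edges of
    either side count), largest first; ties broken by smallest member id."""
    seen: set[str] = set()
    comps: list[set[str]] = []
    for nid in sorted(graph.nodes):
        if nid in seen:
            continue
        comp = {nid}
        queue = deque([nid])
        while queue:
            cur = queue.popleft()
            for nxt in graph.node_neighbors(cur):
                if nxt not in comp:
                    comp.add(nxt)
                    queue.append(nxt)
        seen |= comp
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def biggest_component(graph: BidirectedGraph) -> BidirectedGraph:
    """Induced subgraph on the component with the most nodes (ties go to the
    component containing the lexicographically smallest node id)."""
    if len(graph) == 0:
        raise GraphError("cannot take the biggest component of an empty graph")
    return graph.subgraph(connected_components(graph)[0])


def extract_neighborhood(graph: BidirectedGraph, start: str, size: int) -> BidirectedGraph:
    """Breadth-first neighbourhood of ``size`` nodes around ``start``.

    Nodes are collected in BFS order (neighbours enqueued in sorted id order
    for reproducibility) until ``size`` nodes are gathered or the component
    is exhausted; the induced subgraph is returned.  ``size`` counts nodes,
    not hops.
    """
    if size < 1:
        raise GraphError("neighborhood size must be >= 1")
    graph.node(start)  # raises NodeNotFoundError for unknown start
    collected = {start}
    queue = deque([start])
    while queue and len(collected) < size:
        cur = queue.popleft()
        for nxt in sorted(graph.node_neighbors(cur)):
            if nxt not in collected:
                collected.add(nxt)
                queue.append(nxt)
                if len(collected) == size:
                    break
    return graph.subgraph(collected)
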