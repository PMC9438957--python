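"""bubblechains: bubbles, superbubbles and bubble chains in genome graphs.

Heterozygous variants and population polymorphisms show up in assembly and
pangenome graphs as *bubbles*: places where paths diverge from a shared
source node and reconverge at a shared sink.  This package reads bidirected
graphs from GFA1, enumerates all superbubbles (with simple/insertion
classification and nesting), strings top-level bubbles into linear *bubble
chains*, and offers the supporting operations used when preparing such
graphs: unitig compaction, biggest-connected-component extraction and
neighbourhood cut-outs.
"""

from .bubbles import Bubble, BubbleType, detect_all_bubbles, find_superbubble_from, is_simple
from .chains import BubbleChain, DetectionReport, build_chains, build_report
from .errors import CompactionError, GFAParseError, GraphError, NodeNotFoundError
from .gfa import read_gfa, write_gfa
from .graph import BidirectedGraph, End, Node, Side, reverse_complement
from .ops import biggest_component, compact, connected_components, extract_neighborhood
from .synthetic import (
    DiploidFixtureSpec,
    FixtureTruth,
    make_diploid_graph,
    make_random_graph,
    oracle_superbubbles,
)

__version__ = "0.1.0"

__all__ = [
    "BidirectedGraph", "Node", "End", "Side", "reverse_complement",
    "read_gfa", "write_gfa",
    "compact", "biggest_component", "connected_components", "extract_neighborhood",
    "Bubble", "BubbleType", "find_superbubble_from", "detect_all_bubbles", "is_simple",
    "BubbleChain", "DetectionReport", "build_chains", "build_report",
    "DiploidFixtureSpec", "FixtureTruth", "make_diploid_graph",
    "make_random_graph", "oracle_superbubbles",
    "GraphError", "GFAParseError", "NodeNotFoundError", "CompactionError",
    "detect_bubble_chains",
]


def detect_bubble_chains(graph: BidirectedGraph, compact_first: bool = True):
    """Full detection pipeline on a graph.

    Compacts linear stretches (unless ``compact_first=False``; simplicity
    classification assumes a compacted graph), detects and classifies all
    bubbles, assembles chains and builds the report.

    Returns ``(graph, bubbles, chains, report)`` where ``graph`` is the
    (possibly compacted) graph the results refer to.
    """
    if compact_first:
        graph = compact(graph)
    bubbles = detect_all_bubbles(graph)
    chains = build_chains(graph, bubbles)
    report = build_report(graph, chains, bubbles)
    return graph, bubbles, chains, report
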