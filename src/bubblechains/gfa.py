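"""GFA1 reading and writing for bidirected graphs.

Only S (segment) and L (link) records are interpreted; H, P, W, C and any
other record types are skipped.  Orientation follows standard GFA1
semantics: in ``L u ou v ov cigar``, ``ou='+'`` means the link leaves the
RIGHT side of ``u`` (segment read forward) and ``ou='-'`` its LEFT side;
``ov='+'`` means the link enters the LEFT side of ``v`` and ``ov='-'`` its
RIGHT side.  Overlap CIGARs are restricted to ``<int>M`` (exact-match
overlap, the de Bruijn case) or ``*`` (blunt, overlap 0); anything else is a
parse error rather than a silent approximation.

Files whose path ends in ``.gz`` are transparently decompressed.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .errors import GFAParseError, GraphError
from .graph import BidirectedGraph, End, Side

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"^(\d+)M$")


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _segment_length(fields: Sequence[str], line_no: int) -> Optional[int]:
    """Extract an LN:i: tag value from S-line tag fields, if present."""
    for tag in fields[3:]:
        if tag.startswith("LN:i:"):
            try:
                return int(tag[5:])
            except ValueError:
                raise GFAParseError(f"bad LN tag {tag!r}", line_no) from None
    return None


def read_gfa(path, keep_sequences: bool = True) -> BidirectedGraph:
    """Parse a GFA1 file into a :class:`BidirectedGraph`.

    With ``keep_sequences=False`` sequences are dropped and only their
    lengths retained (from the sequence field itself or an ``LN:i:`` tag).
    Segments declared with ``*`` sequences always require an ``LN:i:`` tag.

    L lines may precede the S lines they reference; referential integrity is
    checked once the whole file has been read.  Duplicate links (including
    the reverse restatement of an already-seen link) are dropped with a
    warning, as are self-links, which are stored but never participate in
    bubbles.
    """
    graph = BidirectedGraph()
    links: list[tuple[int, End, End, int]] = []

    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rec = line.split("\t")
            if rec[0] == "S":
                if len(rec) < 3:
                    raise GFAParseError(
                        f"S line has {len(rec)} fields, need at least 3", line_no
                    )
                name, seq = rec[1], rec[2]
                if name in graph:
                    raise GFAParseError(f"duplicate segment {name!r}", line_no)
                if seq == "*":
                    length = _segment_length(rec, line_no)
                    if length is None:
                        raise GFAParseError(
                            f"segment {name!r} has '*' sequence and no LN:i: tag", line_no
                        )
                    graph.add_node(name, "", length)
                elif keep_sequences:
                    graph.add_node(name, seq)
                else:
                    length = _segment_length(rec, line_no)
                    graph.add_node(name, "", length if length is not None else len(seq))
            elif rec[0] == "L":
                if len(rec) < 6:
                    raise GFAParseError(
                        f"L line has {len(rec)} fields, need 6", line_no
                    )
                _, u, ou, v, ov, cigar = rec[:6]
                if ou not in "+-" or ov not in "+-":
                    raise GFAParseError(f"bad orientation {ou!r}/{ov!r}", line_no)
                if cigar == "*":
                    overlap = 0
                else:
                    m = _CIGAR_RE.match(cigar)
                    if not m:
                        raise GFAParseError(
                            f"unsupported overlap CIGAR {cigar!r} (only '<int>M' or '*')",
                            line_no,
                        )
                    overlap = int(m.group(1))
                from_end = End(u, Side.RIGHT if ou == "+" else Side.LEFT)
                to_end = End(v, Side.LEFT if ov == "+" else Side.RIGHT)
                links.append((line_no, from_end, to_end, overlap))
            # other record types ignored

    for line_no, a, b, overlap in links:
        for end in (a, b):
            if end.node not in graph:
                raise GFAParseError(
                    f"L line references undeclared segment {end.node!r}", line_no
                )
        if a.node == b.node:
            logger.warning("line %d: self-link on segment %r (kept, excluded from bubbles)",
                           line_no, a.node)
        if not graph.add_edge(a, b, overlap):
            logger.warning("line %d: duplicate link %s -- %s dropped", line_no, a, b)
    return graph


def write_gfa(graph: BidirectedGraph, path,
              tags: Optional[Mapping[str, Sequence[str]]] = None) -> None:
    """Write ``graph`` as GFA1: one S line per node (sorted by id, with an
    ``LN:i:`` tag and any extra per-node ``tags``), one L line per undirected
    edge.  Each edge is emitted exactly once, from its canonical direction.
    """
    tags = tags or {}
    path = Path(path)
    out = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "wt")
    with out:
        for nid in sorted(graph.nodes):
            node = graph.nodes[nid]
            if not node.sequence and node.length <= 0:
                raise GraphError(f"node {nid!r} has no sequence and no length; cannot write")
            seq = node.sequence if node.sequence else "*"
            fields = ["S", nid, seq, f"LN:i:{node.length}"]
            fields.extend(tags.get(nid, ()))
            out.write("\t".join(fields) + "\n")
        for a, b, overlap in sorted(graph.edges()):
            ou = "+" if a.side is Side.RIGHT else "-"
            ov = "+" if b.side is Side.LEFT else "-"
            out.write("\t".join(["L", a.node, ou, b.node, ov, f"{overlap}M"]) + "\n")
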