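"""Exception hierarchy."""


class GraphError(Exception):
    """Base class for all errors raised by this package."""


class NodeNotFoundError(GraphError, KeyError):
    """A node id was referenced that is not present in the graph."""

    def __init__(self, node_id: str):
        super().__init__(f"node {node_id!r} not found in graph")
        self.node_id = node_id


class GFAParseError(GraphError, ValueError):
    """A GFA record could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class CompactionError(GraphError):
    """A linear-path merge was impossible (e.g. overlap >= node length)."""
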