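"""Compact a GFA graph, keep its biggest component, cut a neighbourhood.

Writes a small two-component GFA file, then runs the three graph utilities
and prints what each one keeps.  The numbers show that compaction merges
the 3-node linear stretch into one segment, that the biggest component is
chosen by node count, and that a neighbourhood is a node-count-limited BFS.
"""

import tempfile
from pathlib import Path

from bubblechains import biggest_component, compact, extract_neighborhood, read_gfa

gfa_text = """\
S\ta\tACGTACG
S\tb\tCGTTT
S\tc\tTTGGA
S\tx\tAAAA
S\ty\tAAAT
L\ta\t+\tb\t+\t3M
L\tb\t+\tc\t+\t2M
L\tx\t+\ty\t+\t0M
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.gfa"
    path.write_text(gfa_text)
    graph = read_gfa(path)

print(f"input: {len(graph)} nodes in 2 components")

compacted = compact(graph)  # both linear stretches merge: a-b-c and x-y
merged = compacted.nodes["a_b_c"]
print(f"compact: {len(compacted)} nodes ({sorted(compacted.nodes)}); "
      f"{merged.node_id!r} spells {merged.sequence!r}")

big = biggest_component(graph)
print(f"biggest component: {sorted(big.nodes)} ({len(big)} of {len(graph)} nodes)")

hood = extract_neighborhood(graph, "a", size=2)
print(f"neighborhood(a, size=2): {sorted(hood.nodes)}")
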