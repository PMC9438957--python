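# Methods

## Graph model

A bidirected graph stores, per node, a sequence (or just its length) and two
adjacency lists, one per side. An edge joins a side of one node to a side of
another and carries a non-negative overlap in bases; it is stored in both
incident lists, so symmetry is an invariant, not a convention
(`BidirectedGraph.check_symmetry` verifies it after mutating operations).
A *directed node* — a node traversed in a fixed orientation — is represented
by the end it exits from: its children are the ends adjacent to that exit
end, each continued out of the opposite side of the neighbour; its parents
are the ends adjacent to its entry side. This gives the doubled directed
graph implicitly, without building it.

GFA1 reading follows standard semantics: in `L u ou v ov cigar`, `+` on `u`
means the link leaves `u`'s RIGHT side, `+` on `v` that it enters `v`'s
LEFT side. Only `<int>M` and `*` overlap CIGARs are accepted; anything else
is a parse error rather than a silent approximation, because the package's
main use case (de Bruijn graphs) has exact k−1-match overlaps and a
mis-read overlap would corrupt every spelled sequence downstream. Links may
precede the segments they reference; referential integrity is checked after
the whole file is read. Duplicate links (including reverse restatements)
are dropped with a warning; self-links are kept but never appear inside
bubbles. `*` sequences require an `LN:i:` tag. Blunt (0-overlap) and
overlap edges may coexist in one graph; nothing in the algorithms assumes
otherwise.

## Superbubble detection

`find_superbubble_from(graph, source)` is a frontier search over directed
nodes: maintain `seen` (reached) and `visited` (processed) sets, repeatedly
pop a directed node all of whose parents are visited, mark its children
seen, and succeed when the frontier collapses to a single directed node
with nothing else pending. The search aborts on a childless node (tip), on
an edge back to the source (cycle), on re-entering an already-processed
directed node (oriented cycle), and — specific to bidirected graphs — on
reaching any node in both orientations, since the doubled directed subgraph
could then not be consistently acyclic. A candidate sink with an edge back
to the source is rejected, as is an empty interior (an adjacent pair is an
edge, not a bubble).

`detect_all_bubbles` starts this search from both ends of every node,
skipping ends with fewer than two distinct children: a minimal superbubble
headed by a single-child source would imply an equally valid pair starting
at that child, contradicting minimality. Each bubble is discovered twice
(forward from its source, backward from its sink); the two are merged into
one canonical object whose endpoints are the two bubble-facing ends ordered
lexicographically by (node id, side). All iteration is in sorted order, so
detection is deterministic.

**Nesting.** Reachability equality forbids interior nodes from having any
edge leaving the bubble, so a bubble nested inside a superbubble is found
by the same whole-graph sweep that finds its parent; re-running detection
restricted to each interior would recompute identical searches. Parent
links are therefore assigned by minimal node-set containment (a bubble's
nodes, endpoints included, inside another's interior), which is equivalent
and single-pass. The oracle cross-check exercises nested configurations.

**Classification** (meaningful on a compacted graph, which the CLI produces
by default before detecting): *simple* = exactly two interior nodes, each
with one edge per side going to the source and sink ends, and no direct
source–sink edge; *insertion* = one interior node plus a direct
source–sink edge; everything else *super*. Insertion bubbles are excluded
from simple counts because their branch structure (two paths of which one
is empty) is a different biological signal — an indel rather than a
substitution. Counts report all bubbles including nested ones, with nested
simple bubbles also broken out separately, so both the inclusive and the
top-level-only readings are available.

## Chains

Top-level bubbles are linked when exactly two of them meet at a shared
endpoint node; a node where three or more meet links none of them (chains
are linear). Each chain is ordered from its lexicographically smaller outer
endpoint and chains are numbered 1..n by starting end. Chain size is
reported in two units, since either can guide the choice of k when building
graphs: bubbles, and a base-pair span defined as the sum over the chain of
the longest source-to-sink walk through each bubble (node lengths minus
edge overlaps, computed by memoised DFS over the bubble's acyclic oriented
subgraph) with shared endpoint nodes counted once. The JSON report has a
fixed key order and no timestamps, so identical inputs give byte-identical
outputs.

## Compaction, components, neighbourhoods

Compaction merges maximal linear paths: an edge is merged through only when
it is the sole edge on both of its incident ends (a node with two edges on
one side is a junction, because merging through it would change traversal
semantics). Walks start from the sorted-smallest unvisited id, extend in
both directions, and the merged node takes the members' ids joined with
`_`, their oriented sequences concatenated with each overlap trimmed from
the successor's prefix (reverse-complemented where the path traverses a
node right-to-left; lengths summed minus overlaps in length-only mode). An
overlap at least as long as the successor raises an error naming the edge.
A fully circular linear path compacts to one node with a self-loop,
starting from its smallest id. The operation is idempotent by construction
(no mergeable pair survives) and asserted so in tests.

`biggest_component` measures components in node count and breaks ties
toward the component containing the smallest node id. `extract_neighborhood`
collects a fixed *node count* (not hop radius — the count is what bounds a
visualisation; a radius flag would be a straightforward extension) by BFS
with neighbours enqueued in sorted order, then returns the induced
subgraph.

## Synthetic fixtures and the oracle

`make_diploid_graph` emulates the de Bruijn graph of a diploid locus: a
random reference, a second haplotype with planted substitutions, all k-mers
of both haplotypes as nodes with k−1-overlap edges, then compaction.
`min_spacing` is the minimum number of *matching bases between* consecutive
variant units (default k): two SNPs share a variant-free k-mer between them
iff at least k matching bases separate them, so this spacing guarantees one
isolated simple bubble per SNP, and all bubbles lie on a single chain along
the locus. Positions stay at least k from the sequence ends so branches
reconverge rather than ending in tips.

Two haplotypes can never produce a superbubble at a clustered locus — two
sequences give two disjoint paths, which compact to a simple bubble however
many SNPs they contain. A cluster (inter-SNP gap below k, default k/2)
therefore adds two recombinant haplotypes carrying alternating phase across
each cluster and the reference allele elsewhere: four sequences through the
locus, more than two branches, exactly one superbubble per cluster and no
effect anywhere else.

Reference sequences are built greedily so every k-mer is unique, and a
fixture is accepted only if every k-mer across all haplotypes occurs at a
single alignment position; otherwise alleles/sequence are re-drawn. This
deliberately excludes collapsed repeats — the main source of spurious
bubbles in real graphs — so a passing fixture suite demonstrates
correctness of the enumeration, not robustness of biological
interpretation against repeats (`allow_repeats=True` skips the check for
negative tests). The generator also models no sequencing errors, no
indels, and single-strand k-mers (no reverse-complement canonicalisation);
real de Bruijn graphs built from reads differ in all three respects.
Everything is driven by one seeded `random.Random`, so fixtures are
deterministic.

`oracle_superbubbles` is the independent correctness anchor: for every
ordered pair of directed ends it computes forward reachability from the
source (not expanding the sink), backward reachability from the sink (not
expanding the source), and demands set equality, no node present in both
orientations, and acyclicity (Kahn) of the induced directed subgraph.
Minimality discards a pair when an interior directed node forms a valid
pair with the source or the sink; validity for this test permits empty
interiors (otherwise every unitig edge would shield nothing), while
reported bubbles require a non-empty interior. It is exponential-free but
quadratic in ends times BFS, so it is restricted to small graphs (≤ ~15
nodes).

## Problem sizes and numerical choices

The acceptance checks use 500 random graphs of 12 nodes (degree ≤ 3, edge
probability 0.1–0.3, mixed blunt/overlap edges and occasional self-loops)
for oracle equivalence, a {0, 1, 5, 20} × {9, 21, 41} grid of (SNP count,
k) fixtures plus 3-cluster variants for planted recovery, and 100 graphs
each for compaction conservation and GFA round-tripping; the whole script
runs in seconds. Sizes were chosen so the brute-force oracle remains
exhaustive while covering branching, nesting, tips and cycles densely.
There is no floating-point anywhere — all quantities are integral — so the
only "tolerances" are exact equalities. Ties are everywhere broken
lexicographically (component choice, chain ordering, merged-path direction)
purely for reproducibility; no result depends on the tie-break.

## Known limitations

Cyclic variation structures (generalised snarls) are out of scope: a locus
whose doubled subgraph is cyclic, or reachable in both orientations, is
simply not reported as a bubble. GFA2/rGFA, paths (P/W) and containments
(C) are not parsed. Compaction requires overlaps shorter than the successor
node and does not verify that overlapping sequence actually matches.
Chain base-pair span is a convention (longest branch walk), not a claim
about haplotype length through the chain.
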