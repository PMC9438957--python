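# bubblechains

Bubbles, superbubbles and bubble chains in bidirected genome graphs.

Heterozygous variants in an assembly graph, and polymorphisms in a pangenome
graph, appear as *bubbles*: places where paths diverge from a shared source
node and reconverge at a shared sink. `bubblechains` reads GFA1 graphs
(de Bruijn graphs, pangenome graphs; blunt or overlap edges), enumerates all
superbubbles with simple/insertion classification and nesting, strings
top-level bubbles into linear *bubble chains*, and provides the supporting
operations used when preparing such graphs: unitig (linear-path) compaction,
biggest-connected-component extraction and neighbourhood cut-outs.

## The structures it finds

The graphs are **bidirected**: a node has a LEFT and a RIGHT side, and each
edge joins a specific side of one node to a specific side of another, which
encodes the relative strand of the two sequences. A walk enters a node at
one side and leaves at the other.

- A **superbubble** ⟨s, t⟩ is a minimal subgraph between a source node *s*
  and a sink node *t* that is directed and acyclic under the orientation
  induced by entering it from *s*, in which the set of nodes reachable from
  *s* equals the set of nodes from which *t* can be reached, and no interior
  node forms such a pair with *s* or *t*.
- A **simple bubble** is the two-path special case — after compaction,
  exactly two interior nodes, each adjacent only to the source and sink
  ends. Simple bubbles are how isolated heterozygous SNPs materialise in a
  diploid de Bruijn graph.
- An **insertion bubble** has one interior branch in parallel with a direct
  source–sink edge (a length polymorphism). It is counted separately, not
  as a simple bubble.
- A **bubble chain** is a maximal linear run of top-level bubbles in which
  the sink node of one bubble is the source node of the next. Nested
  bubbles are reported inside their enclosing superbubble.

Detection runs the classic frontier search from both oriented ends of every
node (average-case linear time), with directed nodes represented as
(node, orientation) pairs so the doubled directed graph never has to be
materialised; a search that reaches a node in both orientations is aborted.

## Worked example

Generate a diploid de Bruijn fixture with five planted heterozygous SNPs
(k = 21, every SNP at least k matching bases from its neighbours) and
detect its bubbles:

```sh
bubblechains fixture --out fixture.gfa --seq-length 900 --k 21 --n-snps 5 --seed 5
bubblechains bchains --in fixture.gfa --json report.json --gfa tagged.gfa
python -c "import json; print(json.load(open('report.json'))['counts'])"
```

prints

```
{'simple_bubbles': 5, 'superbubbles': 0, 'insertion_bubbles': 0,
 'nested_simple_bubbles': 0, 'chains': 1, 'longest_chain_in_bubbles': 5,
 'longest_chain_in_bases': 900}
```

Each isolated SNP became exactly one simple bubble; all five lie on one
chain whose longest walk spans the 900 bp locus. `tagged.gfa` is the same
graph with a `BC:i:<chain id>` tag on every segment (0 = in no chain). The
same pipeline is available from Python:

```python
from bubblechains import read_gfa, detect_bubble_chains
graph, bubbles, chains, report = detect_bubble_chains(read_gfa("fixture.gfa"))
print(report.counts)
```

The other subcommands are `compact`, `biggestcomp` and `neighborhood`; see
`bubblechains --help` and the `examples/` scripts.

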