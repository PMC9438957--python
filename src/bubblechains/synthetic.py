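"""Synthetic graphs with known bubble structure, and the definitional oracle.

Two generators anchor the test suite:

* :func:`make_diploid_graph` builds the de Bruijn graph of a simulated
  diploid locus: a random reference sequence, a second haplotype with
  planted heterozygous SNPs, all k-mers of both haplotypes as nodes joined
  by (k-1)-overlap edges, then compacted.  Every SNP separated from its
  neighbours by at least k matching bases becomes exactly one simple bubble,
  and all bubbles line up in a single chain along the locus.  SNP *clusters*
  closer than k bases share k-mers between variant sites; to turn such a
  locus into a genuine superbubble (more than two branches) the generator
  adds two recombinant haplotypes carrying mixed phase across each cluster —
  the classical four-sequence construction.  Reference sequences are
  rejection-sampled so that every k-mer is unique within and across
  haplotypes except at aligned positions, which keeps the planted truth
  exact (collapsed repeats, a real-data false-positive source, are
  deliberately absent; pass ``allow_repeats=True`` to skip the check for
  negative tests).

* :func:`make_random_graph` emits small random bidirected graphs (blunt or
  overlap edges, bounded degree) for property tests against
  :func:`oracle_superbubbles`, an exhaustive checker that applies the
  superbubble definition literally to every ordered pair of oriented ends.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Optional

from .bubbles import Bubble, classify
from .graph import BidirectedGraph, End, Side
from .ops import compact

__all__ = [
    "DiploidFixtureSpec",
    "FixtureTruth",
    "make_diploid_graph",
    "make_random_graph",
    "oracle_superbubbles",
]

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# diploid planted-SNP fixture
# ---------------------------------------------------------------------------

@dataclass
class DiploidFixtureSpec:
    """Parameters of a planted-variant diploid de Bruijn fixture.

    ``min_spacing`` is the minimum number of matching bases between
    consecutive variant units; at ``min_spacing >= k`` neighbouring units
    share a variant-free k-mer and therefore produce separate bubbles.
    ``clusters`` adds that many groups of ``cluster_snps`` SNPs whose
    internal gap (default ``k // 2``) is below k, which merges them into one
    superbubble per cluster.
    """

    seq_length: int
    k: int
    n_snps: int
    min_spacing: Optional[int] = None  # defaults to k
    seed: int = 0
    clusters: int = 0
    cluster_snps: int = 2
    cluster_gap: Optional[int] = None  # defaults to max(1, k // 2)

    def __post_init__(self) -> None:
        if self.min_spacing is None:
            self.min_spacing = self.k
        if self.cluster_gap is None:
            self.cluster_gap = max(1, self.k // 2)
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.min_spacing < self.k:
            raise ValueError("min_spacing must be >= k for isolated bubbles")
        if self.clusters and not (1 <= self.cluster_gap < self.k):
            raise ValueError("cluster_gap must be in [1, k) to merge cluster SNPs")
        if self.n_snps < 0 or self.clusters < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class FixtureTruth:
    """Ground truth accompanying a generated fixture."""

    simple_bubbles: int
    superbubbles: int
    chains: int
    snp_positions: list[int]
    cluster_positions: list[list[int]]
    reference: str
    haplotypes: list[str] = field(default_factory=list)


def _random_seq_unique_kmers(rng: random.Random, length: int, k: int,
                             attempts: int = 200) -> str:
    """Random DNA string of ``length`` in which every k-mer occurs once.

    Built greedily, choosing at each position a base whose closing k-mer is
    fresh; restarts on a dead end.  Feasible whenever 4**k comfortably
    exceeds the number of k-mers, which holds for every fixture size used
    here.
    """
    for _ in range(attempts):
        seq: list[str] = []
        kmers: set[str] = set()
        ok = True
        while len(seq) < length:
            placed = False
            for base in rng.sample(_BASES, 4):
                if len(seq) < k - 1:
                    seq.append(base)
                    placed = True
                    break
                kmer = "".join(seq[-(k - 1):]) + base
                if kmer not in kmers:
                    seq.append(base)
                    kmers.add(kmer)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return "".join(seq)
    raise RuntimeError("could not sample a repeat-free sequence; increase length or k")


def _variant_positions(rng: random.Random, spec: DiploidFixtureSpec):
    """Positions for isolated SNPs and cluster SNPs, all >= k from the
    sequence ends and with >= min_spacing matching bases between units."""
    k, gap = spec.k, spec.cluster_gap
    cluster_width = (spec.cluster_snps - 1) * (gap + 1) + 1
    units = ([1] * spec.n_snps) + ([cluster_width] * spec.clusters)
    rng.shuffle(units)
    n_units = len(units)
    if n_units == 0:
        return [], []
    required = k + sum(units) + (n_units - 1) * spec.min_spacing + k
    slack = spec.seq_length - required
    if slack < 0:
        raise ValueError(
            f"seq_length {spec.seq_length} too short for the requested variants "
            f"(need >= {required})")
    extras = sorted(rng.randint(0, slack) for _ in range(n_units))
    extras = [extras[0]] + [b - a for a, b in zip(extras, extras[1:])]

    isolated: list[int] = []
    clusters: list[list[int]] = []
    pos = k
    for width, extra in zip(units, extras):
        pos += extra
        if width == 1:
            isolated.append(pos)
        else:
            clusters.append([pos + i * (gap + 1) for i in range(spec.cluster_snps)])
        pos += width + spec.min_spacing
    return isolated, clusters


def _plant(rng: random.Random, reference: str, positions: list[int]) -> list[str]:
    hap = list(reference)
    for p in positions:
        hap[p] = rng.choice([b for b in _BASES if b != reference[p]])
    return "".join(hap)


def _kmer_truth_holds(haplotypes: list[str], k: int) -> bool:
    """Every k-mer must occur at a single alignment position (and once per
    haplotype), so the union de Bruijn graph mirrors the planted alignment."""
    where: dict[str, set[int]] = {}
    for hap in haplotypes:
        seen: set[str] = set()
        for i in range(len(hap) - k + 1):
            kmer = hap[i:i + k]
            if kmer in seen:
                return False
            seen.add(kmer)
            where.setdefault(kmer, set()).add(i)
    return all(len(s) == 1 for s in where.values())


def make_diploid_graph(spec: DiploidFixtureSpec,
                       compacted: bool = True,
                       allow_repeats: bool = False):
    """Generate the fixture graph and its ground truth.

    Returns ``(graph, truth)``; the graph is compacted unless
    ``compacted=False``.  Deterministic for a fixed spec (including seed).
    """
    rng = random.Random(spec.seed)
    isolated, clusters = _variant_positions(rng, spec)
    cluster_flat = [p for c in clusters for p in c]

    for _ in range(50):
        reference = _random_seq_unique_kmers(rng, spec.seq_length, spec.k)
        haplotypes = [reference, _plant(rng, reference, isolated + cluster_flat)]
        if clusters:
            # two recombinant haplotypes with alternating phase per cluster:
            # reference elsewhere, so they add branches only at cluster loci
            phase_a = [p for c in clusters for p in c[0::2]]
            phase_b = [p for c in clusters for p in c[1::2]]
            alt = haplotypes[1]
            haplotypes.append("".join(
                alt[i] if i in set(phase_a) else reference[i]
                for i in range(len(reference))))
            haplotypes.append("".join(
                alt[i] if i in set(phase_b) else reference[i]
                for i in range(len(reference))))
        if allow_repeats or _kmer_truth_holds(haplotypes, spec.k):
            break
    else:
        raise RuntimeError("failed to build a collision-free fixture")

    graph = BidirectedGraph(k=spec.k)
    ids: dict[str, str] = {}
    for hap in haplotypes:
        prev = None
        for i in range(len(hap) - spec.k + 1):
            kmer = hap[i:i + spec.k]
            nid = ids.get(kmer)
            if nid is None:
                nid = f"n{len(ids)}"
                ids[kmer] = nid
                graph.add_node(nid, kmer)
            if prev is not None:
                graph.add_edge(End(prev, Side.RIGHT), End(nid, Side.LEFT), spec.k - 1)
            prev = nid

    if compacted:
        graph = compact(graph)
    truth = FixtureTruth(
        simple_bubbles=len(isolated),
        superbubbles=len(clusters),
        chains=1 if (isolated or clusters) else 0,
        snp_positions=isolated,
        cluster_positions=clusters,
        reference=reference,
        haplotypes=haplotypes,
    )
    return graph, truth


# ---------------------------------------------------------------------------
# random bidirected graphs
# ---------------------------------------------------------------------------

def make_random_graph(n_nodes: int, edge_prob: float, seed: int,
                      max_degree: int = 3,
                      allow_self_loops: bool = False,
                      overlap_edges: bool = False) -> BidirectedGraph:
    """Small random bidirected graph for oracle-based property tests.

    Candidate side-to-side edges are visited in a seeded random order and
    kept with probability ``edge_prob`` while both incident nodes stay below
    ``max_degree`` total edges.  With ``overlap_edges=True`` each edge gets
    a random overlap shorter than both sequences; otherwise all edges are
    blunt.  Deterministic for a fixed seed.
    """
    rng = random.Random(seed)
    graph = BidirectedGraph()
    names = [f"n{i:02d}" for i in range(n_nodes)]
    for name in names:
        length = rng.randint(4, 8)
        graph.add_node(name, "".join(rng.choice(_BASES) for _ in range(length)))

    ends = [End(n, s) for n in names for s in (Side.LEFT, Side.RIGHT)]
    candidates = [(a, b) for a, b in itertools.combinations(ends, 2)
                  if allow_self_loops or a.node != b.node]
    if allow_self_loops:
        candidates += [(e, e) for e in ends]
    rng.shuffle(candidates)
    for a, b in candidates:
        if rng.random() >= edge_prob:
            continue
        if (graph.node(a.node).degree() >= max_degree
                or graph.node(b.node).degree() >= max_degree):
            continue
        overlap = 0
        if overlap_edges:
            shortest = min(graph.node(a.node).length, graph.node(b.node).length)
            overlap = rng.randint(0, min(3, shortest - 1))
        graph.add_edge(a, b, overlap)
    return graph


# ---------------------------------------------------------------------------
# brute-force superbubble oracle
# ---------------------------------------------------------------------------

def _forward_set(graph: BidirectedGraph, start: End, stop: End) -> set[End]:
    """Directed nodes reachable from ``start``, not expanding ``stop``."""
    reach = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        if v == stop:
            continue
        for u in graph.children(v):
            if u not in reach:
                reach.add(u)
                stack.append(u)
    return reach


def _backward_set(graph: BidirectedGraph, start: End, stop: End) -> set[End]:
    reach = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        if v == stop:
            continue
        for u in graph.parents(v):
            if u not in reach:
                reach.add(u)
                stack.append(u)
    return reach


def _is_acyclic(graph: BidirectedGraph, nodes: set[End]) -> bool:
    """Kahn's algorithm on the directed subgraph induced by ``nodes``."""
    indeg = {v: 0 for v in nodes}
    for v in nodes:
        for u in graph.children(v):
            if u in indeg:
                indeg[u] += 1
    queue = [v for v, d in indeg.items() if d == 0]
    done = 0
    while queue:
        v = queue.pop()
        done += 1
        for u in graph.children(v):
            if u in indeg:
                indeg[u] -= 1
                if indeg[u] == 0:
                    queue.append(u)
    return done == len(nodes)


def _valid_pair(graph: BidirectedGraph, s: End, t: End) -> Optional[set[End]]:
    """Directed-node set of the candidate superbubble <s, t>, or None.

    Checks the definition directly: matching forward/backward reachability,
    no node in both orientations, acyclicity of the induced directed
    subgraph.  An empty interior is allowed here — minimality filtering
    needs trivial pairs — and rejected later for reported bubbles.
    """
    if s.node == t.node:
        return None
    fwd = _forward_set(graph, s, t)
    if t not in fwd:
        return None
    bwd = _backward_set(graph, t, s)
    if s not in bwd or fwd != bwd:
        return None
    if any(v.opposite in fwd for v in fwd):
        return None
    if not _is_acyclic(graph, fwd):
        return None
    return fwd


def oracle_superbubbles(graph: BidirectedGraph) -> list[Bubble]:
    """Exhaustive definitional enumeration of all superbubbles.

    Every ordered pair of directed ends is tested against the definition;
    candidates containing an interior node that itself forms a valid pair
    with the source or the sink are discarded (minimality).  Intended for
    graphs of at most ~15 nodes.  Output is canonical and classified, for
    set comparison with :func:`detect_all_bubbles`.
    """
    ends = [End(n, s) for n in sorted(graph.nodes) for s in (Side.LEFT, Side.RIGHT)]
    valid: dict[tuple[End, End], set[End]] = {}
    for s in ends:
        for t in ends:
            region = _valid_pair(graph, s, t)
            if region is not None:
                valid[(s, t)] = region

    found: dict[tuple[End, End], Bubble] = {}
    for (s, t), region in valid.items():
        interior_dirs = region - {s, t}
        if not interior_dirs:
            continue
        if any((s, v) in valid or (v, t) in valid for v in interior_dirs):
            continue  # an inner node heads/ends a smaller valid pair
        a, b = sorted((s, t.opposite))
        interior = frozenset(v.node for v in interior_dirs)
        prev = found.get((a, b))
        if prev is not None:
            assert prev.interior == interior
            continue
        bubble = Bubble(a, b, interior)
        bubble.btype = classify(graph, bubble)
        found[(a, b)] = bubble
    return sorted(found.values(), key=lambda b: (b.source, b.sink))
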