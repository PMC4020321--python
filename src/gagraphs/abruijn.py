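"""A-Bruijn graph: one vertex per block, directed adjacency multi-edges.

The most compact of the four representations.  Its structure shows neither
inversions nor duplication pairings; the sparse labelings carry exactly the
missing information: ``DupLabels`` totally orders the edges by adjacency
position (pairing incoming and outgoing edges for threading), and
``InvEdgeLabels`` attaches the orientation bits of the two segments meeting
at each adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .core import Block, BlockSet, validate_tiling

__all__ = [
    "ABruijnStructure",
    "ABruijnModel",
    "DupLabels",
    "InvEdgeLabels",
    "build_abruijn",
    "recover_blocks_ab",
    "thread_genome_ab",
]


@dataclass(frozen=True)
class ABruijnStructure:
    """Directed multigraph; every edge is an individually identified object
    (multiple parallel edges rather than multiplicity counters)."""

    vertices: frozenset[str]
    edges: Mapping[str, tuple[str, str]]  # edge id -> (source, target)

    def out_edges(self, v: str) -> list[str]:
        return sorted(e for e, (u, _) in self.edges.items() if u == v)

    def in_edges(self, v: str) -> list[str]:
        return sorted(e for e, (_, w) in self.edges.items() if w == v)


@dataclass(frozen=True)
class ABruijnModel:
    structure: ABruijnStructure
    labels: Mapping[str, Block]  # bijection vertices -> blocks
    genome_lengths: Mapping[str, int]


@dataclass(frozen=True)
class DupLabels:
    """Total order on adjacency edges: ``rank[e1] < rank[e2]`` iff the
    adjacency position of e1 precedes that of e2 in the genome order.

    Ranks are dense (1..|E|) across all genomes.  Each edge also records
    the genome its adjacency belongs to; threading follows each genome
    separately, so the per-genome grouping is part of the duplication
    labeling.
    """

    rank: Mapping[str, int]
    genome: Mapping[str, str]

    def edges_of_genome(self, g: str) -> list[str]:
        return sorted(
            (e for e, gg in self.genome.items() if gg == g),
            key=lambda e: self.rank[e],
        )


InvEdgeLabels = Mapping[str, tuple[str, str]]  # edge -> (source bit, target bit)


def build_abruijn(
    bs: BlockSet,
) -> tuple[ABruijnModel, DupLabels, dict[str, tuple[str, str]]]:
    """Build the A-Bruijn model with both sparse labelings.

    One vertex per block (id = block id); one directed edge per pair of
    adjacent segments, pointing in genomic left-to-right direction.  Edge
    ids ``e1..eN`` follow the duplication ranks.
    """
    problems = validate_tiling(bs)
    if problems:
        raise ValueError("invalid tiling: " + "; ".join(problems))
    labels = {str(b.id): b for b in bs.blocks}
    boundaries = sorted(bs.boundaries(), key=lambda bd: bd.position)
    edges: dict[str, tuple[str, str]] = {}
    rank: dict[str, int] = {}
    genome: dict[str, str] = {}
    inv: dict[str, tuple[str, str]] = {}
    for k, bd in enumerate(boundaries, start=1):
        eid = f"e{k}"
        edges[eid] = (str(bd.left_block.id), str(bd.right_block.id))
        rank[eid] = k
        genome[eid] = bd.position.genome
        inv[eid] = (bd.left_segment.orientation, bd.right_segment.orientation)
    structure = ABruijnStructure(frozenset(labels), edges)
    model = ABruijnModel(structure, labels, dict(bs.genome_lengths))
    return model, DupLabels(rank, genome), inv


def recover_blocks_ab(m: ABruijnModel) -> BlockSet:
    return BlockSet(m.genome_lengths, list(m.labels.values()))


def thread_genome_ab(
    m: ABruijnModel, dup: DupLabels, g: str
) -> list[tuple[str | None, str]]:
    """Follow genome ``g`` through the graph using the duplication labels.

    Returns the walk as ``(edge, vertex)`` pairs; the first pair carries no
    edge.  The vertex sequence is the genome's block order.  Without
    duplications the walk is forced by the structure alone; with
    duplications the labels pair each incoming with the right outgoing edge.
    """
    ranks = list(dup.rank.values())
    if len(set(ranks)) != len(ranks):
        raise ValueError("duplication labels must be a strict total order")
    edge_ids = dup.edges_of_genome(g)
    if not edge_ids:
        # single-segment genome: locate its block through the labels
        for vid, b in sorted(m.labels.items()):
            if any(s.genome == g for s in b.segments):
                return [(None, vid)]
        raise ValueError(f"genome {g!r} not present in the model")
    walk: list[tuple[str | None, str]] = []
    prev_target: str | None = None
    for eid in edge_ids:
        if eid not in m.structure.edges:
            raise ValueError(f"label for unknown edge {eid}")
        u, v = m.structure.edges[eid]
        if prev_target is None:
            walk.append((None, u))
        elif u != prev_target:
            raise ValueError(
                f"duplication labels inconsistent with edges: {eid} starts at"
                f" {u}, expected {prev_target}"
            )
        walk.append((eid, v))
        prev_target = v
    return walk
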