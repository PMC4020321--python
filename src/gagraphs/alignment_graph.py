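"""Alignment graph: one vertex per segment, directed adjacency edges,
undirected block edges.

The vertex labeling maps every vertex to its segment; the structure alone
shows duplications (block edges within one genome) and translocations
(mixed cycles) but not inversions, which require the sparse orientation
labeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .core import Block, BlockSet, Segment, validate_tiling

__all__ = [
    "AlignmentGraphStructure",
    "AlignmentGraphModel",
    "build_alignment_graph",
    "recover_blocks_ag",
    "inv_labels_ag",
]


@dataclass(frozen=True)
class AlignmentGraphStructure:
    """A mixed graph: directed adjacency edges thread the genomes, each
    block forms a block-edge connected clique."""

    vertices: frozenset[str]
    adjacency_edges: frozenset[tuple[str, str]]
    block_edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        outs = [u for u, _ in self.adjacency_edges]
        ins = [v for _, v in self.adjacency_edges]
        if len(outs) != len(set(outs)) or len(ins) != len(set(ins)):
            raise ValueError(
                "each vertex may have at most one incoming and one outgoing"
                " adjacency edge"
            )

    def block_components(self) -> list[frozenset[str]]:
        """Block-edge connected components (each represents one block)."""
        parent: dict[str, str] = {v: v for v in self.vertices}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in self.block_edges:
            u, v = sorted(e)
            parent[find(u)] = find(v)
        comps: dict[str, set[str]] = {}
        for v in self.vertices:
            comps.setdefault(find(v), set()).add(v)
        return sorted((frozenset(c) for c in comps.values()), key=sorted)


@dataclass(frozen=True)
class AlignmentGraphModel:
    structure: AlignmentGraphStructure
    labels: Mapping[str, Segment]  # bijection vertices -> segments
    genome_lengths: Mapping[str, int]


def build_alignment_graph(bs: BlockSet) -> AlignmentGraphModel:
    """Build the alignment graph model of a tiling.

    Vertex ids are ``genome:rank`` with rank the segment's position in its
    genome; ranks make the output deterministic.  A block of size n
    contributes n(n-1)/2 block edges (an explicit clique).
    """
    problems = validate_tiling(bs)
    if problems:
        raise ValueError("invalid tiling: " + "; ".join(problems))
    labels: dict[str, Segment] = {}
    vertex_of: dict[Segment, str] = {}
    adjacency: set[tuple[str, str]] = set()
    for g in bs.genomes:
        order = bs.segments_in_order(g)
        for rank, (s, _b) in enumerate(order):
            vid = f"{g}:{rank}"
            labels[vid] = s
            vertex_of[s] = vid
        for (s1, _), (s2, _) in zip(order, order[1:]):
            adjacency.add((vertex_of[s1], vertex_of[s2]))
    block_edges: set[frozenset[str]] = set()
    for b in bs.blocks:
        vs = [vertex_of[s] for s in b.canonical.segments]
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                block_edges.add(frozenset((vs[i], vs[j])))
    structure = AlignmentGraphStructure(
        frozenset(labels), frozenset(adjacency), frozenset(block_edges)
    )
    return AlignmentGraphModel(structure, labels, dict(bs.genome_lengths))


def recover_blocks_ag(m: AlignmentGraphModel) -> BlockSet:
    """Recover the block set: one block per block-edge connected component."""
    blocks = []
    for comp in m.structure.block_components():
        segs = [m.labels[v] for v in comp]
        blocks.append(Block(min(comp), segs))
    return BlockSet(m.genome_lengths, blocks)


def inv_labels_ag(m: AlignmentGraphModel) -> dict[str, str]:
    """Sparse orientation labeling: '+' for forward segments, '-' for
    reverse-complemented ones."""
    return {v: s.orientation for v, s in m.labels.items()}
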