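"""Enredo graph: two vertices (head/tail) per block joined by an undirected
block edge, plus directed adjacency multi-edges.

The two-vertex concept makes relative block orientation part of the
structure: an adjacency edge leaves a forward segment through the head
vertex and a reverse-complemented one through the tail vertex, and enters a
forward segment at the tail and a reverse-complemented one at the head.
Inversions are therefore visible where alignment and A-Bruijn structures
hide them.  Head and tail are *not* marked in the structure; the block edge
labels, which fix one of the two block representations, mark them
implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .abruijn import DupLabels
from .core import Block, BlockSet, Segment, validate_tiling

__all__ = [
    "EnredoStructure",
    "EnredoModel",
    "build_enredo",
    "recover_blocks_en",
    "collapse_size1_blocks",
    "expand_labeled_adjacencies",
]

BlockEdge = frozenset  # a frozenset of the two endpoint vertex ids


@dataclass(frozen=True)
class EnredoStructure:
    vertices: frozenset[str]
    block_edges: frozenset[BlockEdge]
    adjacency_edges: Mapping[str, tuple[str, str]]  # edge id -> (src, dst)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.block_edges:
            for v in e:
                if v in seen:
                    raise ValueError(
                        f"vertex {v} is an endpoint of more than one block edge"
                    )
                seen.add(v)
        if seen != set(self.vertices):
            raise ValueError(
                "every vertex must be an endpoint of exactly one block edge"
            )

    def adjacency_degree(self, v: str) -> int:
        return sum(
            (u == v) + (w == v) for u, w in self.adjacency_edges.values()
        )


@dataclass(frozen=True)
class EnredoModel:
    """Structure plus labels.

    ``labels`` maps each block edge to its block; choosing the stored
    (canonical) representation implicitly marks ``head_vertex[edge]`` as the
    head end.  ``adjacency_segment_labels`` carries segments of collapsed
    size-1 blocks, when present.
    """

    structure: EnredoStructure
    labels: Mapping[BlockEdge, Block]
    head_vertex: Mapping[BlockEdge, str]
    genome_lengths: Mapping[str, int]
    adjacency_segment_labels: Mapping[str, Segment] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.adjacency_segment_labels is None:
            object.__setattr__(self, "adjacency_segment_labels", {})


def _vertex_ids(block_id: str) -> tuple[str, str]:
    return f"{block_id}.t", f"{block_id}.h"


def build_enredo(bs: BlockSet) -> tuple[EnredoModel, DupLabels]:
    """Build the Enredo model of a tiling, with duplication labels on the
    adjacency edges (same dense position ordering as for A-Bruijn graphs)."""
    problems = validate_tiling(bs)
    if problems:
        raise ValueError("invalid tiling: " + "; ".join(problems))
    vertices: set[str] = set()
    block_edges: set[BlockEdge] = set()
    labels: dict[BlockEdge, Block] = {}
    head_vertex: dict[BlockEdge, str] = {}
    tail_of: dict[str, str] = {}
    head_of: dict[str, str] = {}
    for b in bs.blocks:
        t, h = _vertex_ids(str(b.id))
        vertices.update((t, h))
        e = frozenset((t, h))
        block_edges.add(e)
        labels[e] = b.canonical
        head_vertex[e] = h
        tail_of[str(b.id)] = t
        head_of[str(b.id)] = h
    adjacency: dict[str, tuple[str, str]] = {}
    rank: dict[str, int] = {}
    genome: dict[str, str] = {}
    boundaries = sorted(bs.boundaries(), key=lambda bd: bd.position)
    for k, bd in enumerate(boundaries, start=1):
        b1, b2 = str(bd.left_block.id), str(bd.right_block.id)
        src = head_of[b1] if bd.left_segment.is_forward else tail_of[b1]
        dst = tail_of[b2] if bd.right_segment.is_forward else head_of[b2]
        eid = f"e{k}"
        adjacency[eid] = (src, dst)
        rank[eid] = k
        genome[eid] = bd.position.genome
    structure = EnredoStructure(
        frozenset(vertices), frozenset(block_edges), adjacency
    )
    model = EnredoModel(
        structure, labels, head_vertex, dict(bs.genome_lengths)
    )
    return model, DupLabels(rank, genome)


def recover_blocks_en(m: EnredoModel) -> BlockSet:
    blocks = list(m.labels.values())
    blocks += [
        Block(f"s:{s.genome}:{s.start}", [s])
        for s in m.adjacency_segment_labels.values()
    ]
    return BlockSet(m.genome_lengths, blocks)


def collapse_size1_blocks(m: EnredoModel) -> EnredoModel:
    """Turn interior size-1 blocks into segment-labeled adjacency edges
    (the original Enredo representation of unaligned stretches).

    A size-1 block is collapsed when each of its two vertices is incident to
    exactly one adjacency edge and neither incident edge already carries a
    segment label.  Terminal size-1 blocks (one incident adjacency edge) are
    kept: the replacement rule needs an edge on both sides.  Runs of
    adjacent size-1 blocks are collapsed one block per run; the segment
    label holds a single segment, so a collapsed edge is never collapsed
    again.
    """
    structure = m.structure
    labels = dict(m.labels)
    head_vertex = dict(m.head_vertex)
    adjacency = dict(structure.adjacency_edges)
    seg_labels = dict(m.adjacency_segment_labels)
    block_edges = set(structure.block_edges)
    vertices = set(structure.vertices)
    for e in sorted(block_edges, key=sorted):
        b = labels.get(e)
        if b is None or b.size != 1:
            continue
        h = head_vertex[e]
        (t,) = set(e) - {h}
        ins = [k for k, (_, w) in adjacency.items() if w == t]
        outs = [k for k, (u, _) in adjacency.items() if u == h]
        side = [
            k
            for k, (u, w) in adjacency.items()
            if u in (t, h) or w in (t, h)
        ]
        if len(ins) != 1 or len(outs) != 1 or len(side) != 2:
            continue  # terminal block, or irregular incidence
        e_in, e_out = ins[0], outs[0]
        if e_in in seg_labels or e_out in seg_labels or e_in == e_out:
            continue
        u_x = adjacency[e_in][0]
        w_y = adjacency[e_out][1]
        new_id = f"{e_in}+{e_out}"
        del adjacency[e_in], adjacency[e_out]
        adjacency[new_id] = (u_x, w_y)
        (seg,) = b.canonical.segments
        seg_labels[new_id] = seg
        block_edges.remove(e)
        vertices -= {t, h}
        del labels[e], head_vertex[e]
    structure = EnredoStructure(
        frozenset(vertices), frozenset(block_edges), adjacency
    )
    return EnredoModel(
        structure, labels, head_vertex, dict(m.genome_lengths), seg_labels
    )


def expand_labeled_adjacencies(m: EnredoModel) -> EnredoModel:
    """Inverse of :func:`collapse_size1_blocks`: replace every
    segment-labeled adjacency edge by a size-1 block."""
    adjacency = dict(m.structure.adjacency_edges)
    labels = dict(m.labels)
    head_vertex = dict(m.head_vertex)
    block_edges = set(m.structure.block_edges)
    vertices = set(m.structure.vertices)
    for eid, seg in sorted(m.adjacency_segment_labels.items()):
        if eid not in adjacency:
            raise ValueError(f"segment label on unknown adjacency edge {eid}")
        u_x, w_y = adjacency.pop(eid)
        bid = f"s:{seg.genome}:{seg.start}"
        t, h = _vertex_ids(bid)
        vertices.update((t, h))
        e = frozenset((t, h))
        block_edges.add(e)
        block = Block(bid, [seg if seg.is_forward else seg.reverse_complement()])
        labels[e] = block
        head_vertex[e] = h
        adjacency[f"{eid}.in"] = (u_x, t)
        adjacency[f"{eid}.out"] = (h, w_y)
    structure = EnredoStructure(
        frozenset(vertices), frozenset(block_edges), adjacency
    )
    return EnredoModel(structure, labels, head_vertex, dict(m.genome_lengths), {})
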