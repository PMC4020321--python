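"""The four elementary modifications of a genome alignment, plus the
segmentation finalisation.

Splitting and merging parallel blocks edit the homology prediction (the
local alignments behind the blocks); merging consecutive blocks and cutting
adjacencies drive the segmentation.  All operate on the block set — graph
effects are realised by rebuilding the graphs from the modified set, which
keeps a single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .core import (
    Block,
    BlockSet,
    HEAD,
    Position,
    Segment,
    TAIL,
    adjacencies_between,
    is_breakpoint,
    validate_tiling,
)
from .substructures import maximal_colinear_paths, path_of_block

__all__ = [
    "SegmentationState",
    "FinalSegment",
    "split_block",
    "merge_parallel_blocks",
    "merge_consecutive_blocks",
    "cut_adjacency",
    "finalize_segmentation",
]


@dataclass(frozen=True)
class SegmentationState:
    """Explicitly fixed breakpoint positions.  Cuts only ever accumulate."""

    cuts: frozenset[Position] = frozenset()

    def with_cuts(self, positions: Iterable[Position]) -> "SegmentationState":
        return SegmentationState(self.cuts | frozenset(positions))


class FinalSegment(NamedTuple):
    genome: str
    start: int
    end: int
    path_index: int  # index of the owning maximal colinear path


def _replace(bs: BlockSet, remove: Iterable[Block], add: Iterable[Block]) -> BlockSet:
    removed = list(remove)
    blocks = [b for b in bs.blocks if all(b != r for r in removed)]
    blocks.extend(add)
    return BlockSet(bs.genome_lengths, blocks)


def _normalise_subset(b: Block, subset: Iterable[Segment]) -> set[Segment]:
    """Map the requested segments onto the block's canonical representation
    (either representation of each segment is accepted)."""
    canonical = set(b.canonical.segments)
    out: set[Segment] = set()
    for s in subset:
        if s in canonical:
            out.add(s)
        elif s.reverse_complement() in canonical:
            out.add(s.reverse_complement())
        else:
            raise ValueError(f"{s} is not a segment of block {b.id}")
    return out


def split_block(bs: BlockSet, b: Block, subset: Iterable[Segment]) -> BlockSet:
    """Replace ``b`` by two blocks: the given proper nonempty subset of its
    segments, and the rest.  Size-1 results are allowed; the tiling is
    untouched."""
    if all(b != x for x in bs.blocks):
        raise ValueError(f"block {b.id} not in the block set")
    chosen = _normalise_subset(b, subset)
    rest = set(b.canonical.segments) - chosen
    if not chosen or not rest:
        raise ValueError("subset must be a proper nonempty subset")
    return _replace(
        bs,
        [b],
        [Block(f"{b.id}/1", chosen), Block(f"{b.id}/2", rest)],
    )


def merge_parallel_blocks(
    bs: BlockSet, b1: Block, b2: Block, orientation: str = "same"
) -> BlockSet:
    """Merge two blocks into one of size |b1|+|b2|, implicitly aligning all
    their segments.  ``orientation`` fixes the relative orientation of
    b2's segments against b1's canonical representation ('same' or
    'opposite')."""
    if b1 == b2:
        raise ValueError("cannot merge a block with itself")
    if orientation not in ("same", "opposite"):
        raise ValueError("orientation must be 'same' or 'opposite'")
    second = b2.canonical if orientation == "same" else b2.canonical.flipped()
    merged = Block(
        f"{b1.id}+{b2.id}", b1.canonical.segments + second.segments
    )
    return _replace(bs, [b1, b2], [merged])


def merge_consecutive_blocks(bs: BlockSet, b1: Block, b2: Block) -> BlockSet:
    """Concatenate two blocks joined by a breakpoint-free adjacency into a
    single longer block.

    Requires equal sizes and an adjacency covering every segment of both
    blocks; the pairing of segments is then unique (via the adjacency
    positions).  The alignment of the genomes is unchanged — only the graph
    structures and the eventual segmentation get simpler.
    """
    if b1 == b2:
        raise ValueError("cannot concatenate a block with itself")
    if b1.size != b2.size:
        raise ValueError("blocks of different size cannot be concatenated")
    full = [
        ac
        for ac in adjacencies_between(b1, b2, bs)
        if not is_breakpoint(ac, b1, b2)
    ]
    if not full:
        raise ValueError(
            f"no breakpoint-free adjacency between {b1.id} and {b2.id}"
        )
    ac = full[0]
    second = b2.canonical
    # flip b2's representation for the orientation-discordant classes so
    # that every adjacent pair reads in one direction
    if ac.block1_end == ac.block2_end:
        second = second.flipped()
    by_boundary_1 = {}
    for s in b1.canonical.segments:
        for off in (s.start, s.end):
            by_boundary_1[Position(s.genome, off)] = s
    by_boundary_2 = {}
    for s in second.segments:
        for off in (s.start, s.end):
            by_boundary_2[Position(s.genome, off)] = s
    merged_segments = []
    for pos in ac.positions:
        s1 = by_boundary_1[pos]
        s2 = by_boundary_2[pos]
        upstream, downstream = (
            (s1, s2) if s1.end == pos.offset else (s2, s1)
        )
        if upstream.is_forward:
            merged_segments.append(
                Segment(pos.genome, upstream.p, downstream.q)
            )
        else:
            merged_segments.append(
                Segment(pos.genome, downstream.p, upstream.q)
            )
    return _replace(
        bs, [b1, b2], [Block(f"{b1.id}{b2.id}", merged_segments)]
    )


def cut_adjacency(
    state: SegmentationState, b: Block, end: str
) -> SegmentationState:
    """Fix a breakpoint at one end of a block: record a cut at the
    corresponding endpoint of every segment.  The block set itself is not
    affected — cutting is part of the segmentation, not of the homology
    prediction."""
    if end not in (HEAD, TAIL):
        raise ValueError("end must be 'head' or 'tail'")
    canonical = b.canonical
    positions = [
        s.p_position() if end == HEAD else s.q_position()
        for s in canonical.segments
    ]
    return state.with_cuts(positions)


def finalize_segmentation(
    bs: BlockSet, state: SegmentationState | None = None
) -> list[FinalSegment]:
    """The final genome segmentation: segments bounded exactly by the
    breakpoints of the maximal colinear paths, the explicit cuts, and the
    genome termini."""
    problems = validate_tiling(bs)
    if problems:
        raise ValueError("invalid tiling: " + "; ".join(problems))
    cuts = state.cuts if state is not None else frozenset()
    paths = maximal_colinear_paths(bs)
    owner = path_of_block(paths)
    path_index = {p: i for i, p in enumerate(paths)}
    out: list[FinalSegment] = []
    for g in bs.genomes:
        order = bs.segments_in_order(g)
        if not order:
            continue
        length = bs.genome_lengths[g]
        boundary_offsets = {0, length}
        boundary_offsets |= {
            pos.offset for pos in cuts if pos.genome == g
        }
        for (s1, b1), (s2, b2) in zip(order, order[1:]):
            off = s1.end
            classes = adjacencies_between(b1, b2, bs)
            cls = next(
                ac
                for ac in classes
                if Position(g, off) in ac.positions
            )
            if is_breakpoint(cls, b1, b2):
                boundary_offsets.add(off)
        offsets = sorted(boundary_offsets)
        for a, b in zip(offsets, offsets[1:]):
            block_at = next(
                blk for s, blk in order if s.start <= a < s.end
            )
            out.append(FinalSegment(g, a, b, path_index[owner[block_at]]))
    return out
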