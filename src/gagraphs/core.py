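"""Core data model for block-based genome alignments.

A genome alignment is represented as a set of *blocks*, where each block is
a colinear alignment of genomic *segments*.  The block set is required to be
a *tiling*: every position of every genome is covered by exactly one segment,
with size-1 filler blocks for unaligned stretches.  All four genome-alignment
graph representations in this package are built from, and can be reduced back
to, this one exchange object.

Coordinates are 0-based and half-open.  A segment is an ordered endpoint pair
``(p, q)``; the order encodes orientation: ``p < q`` is the forward strand,
``p > q`` the reverse complement.  The segment covers offsets
``[min(p, q), max(p, q))``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

HEAD = "head"
TAIL = "tail"

__all__ = [
    "HEAD",
    "TAIL",
    "Position",
    "Segment",
    "Block",
    "BlockSet",
    "AdjacencyClass",
    "SegmentRelation",
    "segments_relation",
    "is_colinear",
    "validate_tiling",
    "adjacencies_between",
    "is_breakpoint",
    "genome_boundaries",
]


@dataclass(frozen=True, order=True)
class Position:
    """A genomic position ``(g, i)``: the (i+1)st character of genome g.

    Positions are totally ordered, first by genome identifier
    (lexicographically) and then by offset.  An offset equal to the genome
    length is permitted only as a segment endpoint (the position directly
    following the last character).
    """

    genome: str
    offset: int


@dataclass(frozen=True)
class Segment:
    """An ordered pair of endpoints on one genome; order encodes strand."""

    genome: str
    p: int
    q: int

    def __post_init__(self) -> None:
        if self.p == self.q:
            raise ValueError(f"segment endpoints must differ: {self}")
        if self.p < 0 or self.q < 0:
            raise ValueError(f"negative endpoint: {self}")

    @property
    def is_forward(self) -> bool:
        return self.p < self.q

    @property
    def orientation(self) -> str:
        return "+" if self.is_forward else "-"

    @property
    def start(self) -> int:
        """Smallest covered offset."""
        return min(self.p, self.q)

    @property
    def end(self) -> int:
        """Offset directly following the largest covered offset."""
        return max(self.p, self.q)

    @property
    def length(self) -> int:
        return abs(self.p - self.q)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def reverse_complement(self) -> "Segment":
        return Segment(self.genome, self.q, self.p)

    def p_position(self) -> Position:
        return Position(self.genome, self.p)

    def q_position(self) -> Position:
        return Position(self.genome, self.q)

    def end_at_boundary(self, offset: int) -> str:
        """Which block end (head/tail) of the owning block this segment
        presents at boundary ``offset``.

        The head of a block collects the ``p`` endpoints of its segments and
        the tail the ``q`` endpoints, under the block's chosen representation.
        At its right boundary (``end``) a forward segment presents ``q`` but
        genome threading leaves a forward segment through the *head* vertex;
        we follow the edge-endpoint convention used by the two-vertex
        (Enredo-style) graph throughout: a forward segment enters at the tail
        and exits at the head, a reverse-complemented segment enters at the
        head and exits at the tail.
        """
        if offset == self.end:  # exit side (right boundary)
            return HEAD if self.is_forward else TAIL
        if offset == self.start:  # entry side (left boundary)
            return TAIL if self.is_forward else HEAD
        raise ValueError(f"{offset} is not a boundary of {self}")


class SegmentRelation(NamedTuple):
    kind: str  # different-genomes | non-overlapping | adjacent |
    #            fully-overlapping | partially-overlapping
    position: Position | None = None  # adjacency position, if adjacent


def segments_relation(s1: Segment, s2: Segment) -> SegmentRelation:
    """Classify the positional relation of two segments.

    Total function, symmetric up to which segment precedes.  Two segments
    sharing exactly one boundary are *adjacent* and define an adjacency at
    that shared boundary position.
    """
    if s1.genome != s2.genome:
        return SegmentRelation("different-genomes")
    a, b = sorted((s1, s2), key=lambda s: (s.start, s.end))
    if a.span == b.span:
        return SegmentRelation("fully-overlapping")
    if a.end == b.start:
        return SegmentRelation("adjacent", Position(a.genome, a.end))
    if a.end < b.start:
        return SegmentRelation("non-overlapping")
    return SegmentRelation("partially-overlapping")


def is_colinear(
    components: Sequence[Iterable[Position]], segments: Iterable[Segment]
) -> bool:
    """Decide whether an alignment (a set of columns) of ``segments`` is
    colinear.

    The alignment is colinear iff every column holds at most one position per
    segment and a strict total order on the columns exists that respects each
    segment's reading direction.  Positions outside all segments are
    rejected.
    """
    segs = list(segments)

    def owner(pos: Position) -> int:
        for i, s in enumerate(segs):
            if s.genome == pos.genome and s.start <= pos.offset < s.end:
                return i
        raise ValueError(f"position {pos} lies outside all segments")

    cols = [frozenset(c) for c in components]
    # column -> {segment index -> position}
    placements: list[dict[int, Position]] = []
    for col in cols:
        seen: dict[int, Position] = {}
        for pos in col:
            i = owner(pos)
            if i in seen:
                return False  # two positions of one segment in one column
            seen[i] = pos
        placements.append(seen)

    # Precedence constraints between columns; detect cycles.
    n = len(cols)
    succ: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in itertools.permutations(range(n), 2):
        for k, p1 in placements[i].items():
            p2 = placements[j].get(k)
            if p2 is None:
                continue
            if p1 == p2:
                return False  # one position in two columns is unorderable
            fwd = segs[k].is_forward
            if (p1 < p2) == fwd:
                succ[i].add(j)
    # acyclic <=> a consistent strict total order exists
    color = [0] * n  # 0 white, 1 gray, 2 black

    def dfs(u: int) -> bool:
        color[u] = 1
        for v in succ[u]:
            if color[v] == 1 or (color[v] == 0 and dfs(v)):
                return True
        color[u] = 2
        return False

    return not any(color[u] == 0 and dfs(u) for u in range(n))


@dataclass(frozen=True)
class Block:
    """A colinear alignment of segments; the atomic homology unit.

    A block has two equivalent representations (as given, or with every
    segment reverse-complemented); both denote the same block with head and
    tail swapped.  Equality and hashing use the canonical representation, in
    which the segment with the smallest minimum position is forward.  Only
    the segment set and relative orientations are modelled; column-level
    alignment detail inside the block is deliberately out of scope.
    """

    id: str
    segments: tuple[Segment, ...]

    def __init__(self, id: str, segments: Iterable[Segment]):
        segs = tuple(sorted(segments, key=lambda s: (s.genome, s.start, s.end)))
        if not segs:
            raise ValueError("a block needs at least one segment")
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "segments", segs)

    @property
    def size(self) -> int:
        return len(self.segments)

    @cached_property
    def canonical(self) -> "Block":
        """The representation whose first segment (smallest min position)
        is forward."""
        first = min(self.segments, key=lambda s: (s.genome, s.start))
        if first.is_forward:
            return self
        return self.flipped()

    def flipped(self) -> "Block":
        """The other representation: all segments reverse-complemented."""
        return Block(self.id, (s.reverse_complement() for s in self.segments))

    @property
    def head(self) -> frozenset[Position]:
        return frozenset(s.p_position() for s in self.segments)

    @property
    def tail(self) -> frozenset[Position]:
        return frozenset(s.q_position() for s in self.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Block):
            return NotImplemented
        return frozenset(self.canonical.segments) == frozenset(
            other.canonical.segments
        )

    def __hash__(self) -> int:
        return hash(frozenset(self.canonical.segments))

    def __repr__(self) -> str:
        return f"Block({self.id!r}, size={self.size})"


@dataclass(frozen=True)
class AdjacencyClass:
    """One of the up-to-four adjacencies between an ordered block pair.

    ``block1_end``/``block2_end`` name the block ends meeting at the
    adjacency (under the blocks' canonical representations); ``positions``
    are the boundary positions at which segments of the two blocks abut.
    """

    block1_end: str
    block2_end: str
    positions: frozenset[Position]


class Boundary(NamedTuple):
    """An internal genome boundary between two consecutive segments."""

    position: Position
    left_segment: Segment
    left_block: Block
    right_segment: Segment
    right_block: Block


@dataclass(frozen=True)
class BlockSet:
    """A set of blocks tiling a set of genomes."""

    genome_lengths: Mapping[str, int]
    blocks: tuple[Block, ...]

    def __init__(self, genome_lengths: Mapping[str, int], blocks: Iterable[Block]):
        object.__setattr__(self, "genome_lengths", dict(genome_lengths))
        object.__setattr__(
            self, "blocks", tuple(sorted(blocks, key=lambda b: str(b.id)))
        )

    @property
    def genomes(self) -> list[str]:
        return sorted(self.genome_lengths)

    def block_by_id(self, block_id: str) -> Block:
        for b in self.blocks:
            if b.id == block_id:
                return b
        raise KeyError(block_id)

    @cached_property
    def _segment_owner(self) -> dict[Segment, Block]:
        owner: dict[Segment, Block] = {}
        for b in self.blocks:
            for s in b.canonical.segments:
                owner[s] = b
        return owner

    def segments_in_order(self, genome: str) -> list[tuple[Segment, Block]]:
        """All segments of one genome in genomic (left-to-right) order,
        in their blocks' canonical representation."""
        pairs = [
            (s, b) for s, b in self._segment_owner.items() if s.genome == genome
        ]
        pairs.sort(key=lambda sb: sb[0].start)
        return pairs

    def boundaries(self) -> Iterator[Boundary]:
        """Every internal segment boundary of every genome, in position
        order.  Genome termini are not boundaries."""
        for g in self.genomes:
            order = self.segments_in_order(g)
            for (s1, b1), (s2, b2) in zip(order, order[1:]):
                yield Boundary(Position(g, s1.end), s1, b1, s2, b2)

    def total_segment_length(self) -> int:
        return sum(s.length for b in self.blocks for s in b.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BlockSet):
            return NotImplemented
        return dict(self.genome_lengths) == dict(other.genome_lengths) and set(
            self.blocks
        ) == set(other.blocks)

    def __hash__(self) -> int:
        return hash(
            (frozenset(self.genome_lengths.items()), frozenset(self.blocks))
        )


def validate_tiling(bs: BlockSet) -> list[str]:
    """Check the tiling invariants; return a list of violation messages
    (empty list = ok).

    The segments of all blocks must cover every offset of every genome
    exactly once, blocks must be pairwise non-overlapping, and every segment
    must reference a known genome.
    """
    violations: list[str] = []
    covered: dict[str, list[tuple[int, int, str]]] = {
        g: [] for g in bs.genome_lengths
    }
    for b in bs.blocks:
        for s in b.segments:
            if s.genome not in bs.genome_lengths:
                violations.append(
                    f"block {b.id}: segment {s} references unknown genome"
                )
                continue
            if s.end > bs.genome_lengths[s.genome]:
                violations.append(
                    f"block {b.id}: segment {s} extends past end of genome"
                )
                continue
            covered[s.genome].append((s.start, s.end, str(b.id)))
    for g, spans in covered.items():
        spans.sort()
        cursor = 0
        for start, end, bid in spans:
            if start < cursor:
                violations.append(
                    f"genome {g}: overlapping segments at offset {start}"
                    f" (block {bid})"
                )
            elif start > cursor:
                violations.append(
                    f"genome {g}: uncovered offsets [{cursor}, {start})"
                )
            cursor = max(cursor, end)
        if cursor < bs.genome_lengths[g]:
            violations.append(
                f"genome {g}: uncovered offsets"
                f" [{cursor}, {bs.genome_lengths[g]})"
            )
    return violations


def adjacencies_between(
    b1: Block, b2: Block, bs: BlockSet
) -> frozenset[AdjacencyClass]:
    """All adjacency classes between two blocks (``b1 == b2`` allowed:
    a block can be adjacent to itself).

    At most four classes exist per block pair (head/tail x head/tail).  The
    end names follow the canonical representations of the blocks; for two
    distinct blocks a class is independent of genomic order (reading a
    boundary from the other strand swaps both roles at once), for a
    self-adjacency the first end is the upstream segment's.
    """
    grouped: dict[tuple[str, str], set[Position]] = {}
    for bd in bs.boundaries():
        off = bd.position.offset
        if bd.left_block == b1 and bd.right_block == b2:
            key = (
                bd.left_segment.end_at_boundary(off),
                bd.right_segment.end_at_boundary(off),
            )
        elif bd.left_block == b2 and bd.right_block == b1 and b1 != b2:
            key = (
                bd.right_segment.end_at_boundary(off),
                bd.left_segment.end_at_boundary(off),
            )
        else:
            continue
        # segments from boundaries() are already in canonical representation
        grouped.setdefault(key, set()).add(bd.position)
    return frozenset(
        AdjacencyClass(e1, e2, frozenset(ps)) for (e1, e2), ps in grouped.items()
    )


def is_breakpoint(ac: AdjacencyClass, b1: Block, b2: Block) -> bool:
    """An adjacency is a breakpoint if the two blocks are adjacent in only a
    subset of their segments (checked against both block sizes)."""
    n = len(ac.positions)
    return n < b1.size or n < b2.size


def genome_boundaries(bs: BlockSet, genome: str) -> list[int]:
    """Internal boundary offsets of one genome (termini excluded)."""
    order = bs.segments_in_order(genome)
    return [s.end for s, _ in order[:-1]]
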