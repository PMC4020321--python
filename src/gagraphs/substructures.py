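"""Detectors for the four substructure classes: colinear paths, visiting
blocks, genome-alignment cycles (whirls, bulges, palindromes), and the
cactus-level chains and groups.

Detectors operate on the block-set / model level, where every substructure
is decidable; which graph *structure* reveals a substructure without label
information is reported separately by :func:`visibility`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

from .core import (
    Block,
    BlockSet,
    HEAD,
    TAIL,
    adjacencies_between,
    is_breakpoint,
    validate_tiling,
)
from .enredo import EnredoModel, build_enredo, recover_blocks_en

__all__ = [
    "ColinearPath",
    "GenomeAlignmentCycle",
    "VisitingBlock",
    "maximal_colinear_paths",
    "path_of_block",
    "detect_visiting_blocks",
    "find_cycles",
    "classify_cycle_orientation",
    "count_cycle_paths",
    "detect_palindromes",
    "visibility",
]


@dataclass(frozen=True)
class ColinearPath:
    """A run of equally sized blocks consecutive in one or more genomes
    without intervening breakpoints; bounded by breakpoints or termini when
    maximal."""

    blocks: tuple[Block, ...]
    maximal: bool = True

    @property
    def size(self) -> int:
        return self.blocks[0].size

    def __contains__(self, b: Block) -> bool:
        return b in self.blocks


@dataclass(frozen=True)
class VisitingBlock:
    """A maximal colinear path all of whose traversals between a specific
    flanking pair continue consistently: segments entering from ``b0``
    leave into ``b_next`` and vice versa."""

    path: ColinearPath
    witnesses: tuple[tuple[Block, Block], ...]


@dataclass(frozen=True)
class GenomeAlignmentCycle:
    """A cyclic block sequence joined by pairwise disjoint adjacencies;
    corresponds to a simple mixed cycle of the Enredo structure."""

    blocks: frozenset[Block]
    adjacency_edges: tuple[str, ...]  # Enredo adjacency edge ids, cycle order
    signs: tuple[int, ...]  # +1 along / -1 against the traversal per edge
    genomes: tuple[str, ...]  # owning genome per adjacency edge
    total_length: int


def _full_links(bs: BlockSet) -> dict[tuple[Block, str], tuple[Block, str]]:
    """Breakpoint-free adjacencies: block end -> linked block end.  A block
    end supports at most one full adjacency (its boundary positions are a
    single set)."""
    links: dict[tuple[Block, str], tuple[Block, str]] = {}
    # self-adjacencies never extend a colinear path, hence combinations
    for b1, b2 in itertools.combinations(bs.blocks, 2):
        for ac in adjacencies_between(b1, b2, bs):
            if is_breakpoint(ac, b1, b2):
                continue
            key1, key2 = (b1, ac.block1_end), (b2, ac.block2_end)
            links[key1] = key2
            links[key2] = key1
    return links


def maximal_colinear_paths(bs: BlockSet) -> list[ColinearPath]:
    """The maximal colinear paths; they partition the blocks."""
    problems = validate_tiling(bs)
    if problems:
        raise ValueError("invalid tiling: " + "; ".join(problems))
    links = _full_links(bs)
    paths: list[ColinearPath] = []
    seen: set[Block] = set()
    for start in bs.blocks:
        if start in seen:
            continue
        # phase 1: follow head-side links to one extremity (or around a
        # cycle of full links, which is cut at the starting block)
        b, exit_end = start, HEAD
        guard = {start}
        while (b, exit_end) in links:
            nb, entry_end = links[(b, exit_end)]
            if nb in guard:
                break
            guard.add(nb)
            b, exit_end = nb, _other(entry_end)
        # phase 2: collect the chain walking back the other way
        chain = [b]
        seen.add(b)
        cur = (b, _other(exit_end))
        while cur in links:
            nb, entry_end = links[cur]
            if nb in seen:
                break
            chain.append(nb)
            seen.add(nb)
            cur = (nb, _other(entry_end))
        if str(chain[0].id) > str(chain[-1].id):
            chain.reverse()  # deterministic orientation
        paths.append(ColinearPath(tuple(chain)))
    return paths


def _other(end: str) -> str:
    return TAIL if end == HEAD else HEAD


def path_of_block(
    paths: Iterable[ColinearPath],
) -> dict[Block, ColinearPath]:
    out: dict[Block, ColinearPath] = {}
    for p in paths:
        for b in p.blocks:
            out[b] = p
    return out


def _path_runs(
    bs: BlockSet, path: ColinearPath
) -> list[tuple[Block | None, Block | None]]:
    """Per traversal of the path, the flanking blocks at its two ends
    (entry flank first; None at a genome terminus).

    Because path-internal adjacencies are breakpoint-free, every occurrence
    of a path block lies on a complete traversal of the whole path.
    """
    members = set(path.blocks)
    first, last = path.blocks[0], path.blocks[-1]
    runs: list[tuple[Block | None, Block | None]] = []
    for g in bs.genomes:
        order = bs.segments_in_order(g)
        i = 0
        while i < len(order):
            if order[i][1] not in members:
                i += 1
                continue
            j = i
            while j + 1 < len(order) and order[j + 1][1] in members:
                j += 1
            left = order[i - 1][1] if i > 0 else None
            right = order[j + 1][1] if j + 1 < len(order) else None
            # orient the run: the entry flank is the one next to the path's
            # first block; a single-block path enters at its canonical tail
            if len(path.blocks) > 1:
                forward = order[i][1] == first
            else:
                s = order[i][0]
                forward = s.end_at_boundary(s.start) == TAIL
            runs.append((left, right) if forward else (right, left))
            i = j + 1
    del last
    return runs


def detect_visiting_blocks(bs: BlockSet) -> list[VisitingBlock]:
    """Maximal colinear paths that are visiting blocks.

    A path is a visiting block for a flanking pair (b0, b_next) when every
    traversal entering from b0 exits into b_next and every traversal
    exiting into b_next entered from b0 (both blocks outside the path,
    at least one such traversal).
    """
    out: list[VisitingBlock] = []
    for path in maximal_colinear_paths(bs):
        runs = _path_runs(bs, path)
        members = set(path.blocks)
        candidates = sorted(
            {
                (e, x)
                for e, x in runs
                if e is not None and x is not None
                and e not in members and x not in members
            },
            key=lambda p: (str(p[0].id), str(p[1].id)),
        )
        witnesses = []
        for b0, b_next in candidates:
            entering = [r for r in runs if r[0] == b0]
            exiting = [r for r in runs if r[1] == b_next]
            if not entering:
                continue
            if all(r[1] == b_next for r in entering) and all(
                r[0] == b0 for r in exiting
            ):
                witnesses.append((b0, b_next))
        if witnesses:
            out.append(VisitingBlock(path, tuple(witnesses)))
    return out


def _enredo_cycles(
    m: EnredoModel,
    dup_genome: Mapping[str, str],
    max_edges_per_cycle: int = 16,
    max_cycles: int = 10_000,
) -> list[GenomeAlignmentCycle]:
    """Enumerate simple mixed cycles of the Enredo structure that contain
    at least one adjacency edge, no two adjacency edges from the same
    adjacency class, and at least two edges."""
    en = m.structure
    block_of_vertex: dict[str, Block] = {}
    partner: dict[str, str] = {}
    for e, b in m.labels.items():
        u, v = sorted(e)
        block_of_vertex[u] = b
        block_of_vertex[v] = b
        partner[u], partner[v] = v, u

    # incident adjacency edges per vertex, with traversal sign
    incident: dict[str, list[tuple[str, str, int]]] = {v: [] for v in en.vertices}
    for eid, (u, v) in en.adjacency_edges.items():
        incident[u].append((eid, v, +1))
        incident[v].append((eid, u, -1))

    # class key per adjacency edge: the unordered (vertex, vertex) endpoint
    # pair identifies the adjacency class at model level
    class_of = {
        eid: frozenset((u, v) if u != v else (u,))
        for eid, (u, v) in en.adjacency_edges.items()
    }

    cycles: dict[frozenset[str], GenomeAlignmentCycle] = {}
    order = sorted(en.vertices)
    index = {v: i for i, v in enumerate(order)}

    def record(edge_seq: list[tuple[str, int]], vertex_seq: list[str]) -> None:
        key = frozenset(e for e, _ in edge_seq)
        if key in cycles:
            return
        blocks = frozenset(block_of_vertex[v] for v in vertex_seq)
        total = sum(s.length for b in blocks for s in b.segments)
        genomes = tuple(
            dup_genome.get(e, "?") for e, _ in edge_seq
        )
        cycles[key] = GenomeAlignmentCycle(
            blocks,
            tuple(e for e, _ in edge_seq),
            tuple(s for _, s in edge_seq),
            genomes,
            total,
        )

    def dfs(
        start: str,
        cur: str,
        via_block: bool,
        vertex_seq: list[str],
        edge_seq: list[tuple[str, int]],
        used_classes: set[frozenset],
        visited: set[str],
    ) -> None:
        if len(cycles) >= max_cycles or len(edge_seq) > max_edges_per_cycle:
            return
        # option 1: cross the block edge (if we arrived via an adjacency)
        if not via_block:
            nxt = partner[cur]
            if nxt == start and len(edge_seq) >= 1 and len(vertex_seq) >= 2:
                record(edge_seq, vertex_seq)
            elif nxt not in visited and index[nxt] > index[start]:
                visited.add(nxt)
                vertex_seq.append(nxt)
                dfs(start, nxt, True, vertex_seq, edge_seq, used_classes, visited)
                vertex_seq.pop()
                visited.remove(nxt)
        # option 2: follow an adjacency edge (in either direction)
        for eid, nxt, sign in sorted(incident[cur]):
            if any(eid == e for e, _ in edge_seq):
                continue
            if class_of[eid] in used_classes:
                continue
            if nxt == start:
                if len(edge_seq) + 1 >= 2 and class_of[eid] not in used_classes:
                    record(edge_seq + [(eid, sign)], vertex_seq)
                continue
            if nxt in visited or index[nxt] < index[start]:
                continue
            visited.add(nxt)
            vertex_seq.append(nxt)
            used_classes.add(class_of[eid])
            edge_seq.append((eid, sign))
            dfs(start, nxt, False, vertex_seq, edge_seq, used_classes, visited)
            edge_seq.pop()
            used_classes.remove(class_of[eid])
            vertex_seq.pop()
            visited.remove(nxt)

    for start in order:
        dfs(start, start, False, [start], [], set(), {start})
    return sorted(
        cycles.values(), key=lambda c: (len(c.adjacency_edges), c.adjacency_edges)
    )


def find_cycles(
    bs: BlockSet,
    max_total_length: int | None = None,
    max_edges_per_cycle: int = 16,
    max_cycles: int = 10_000,
) -> list[GenomeAlignmentCycle]:
    """Genome alignment cycles, as simple mixed cycles of the Enredo
    structure.

    A cycle is *short* when the total segment length of its blocks is below
    ``max_total_length``; pass None to disable the threshold (it has no
    universal default and is a tuning parameter).
    """
    m, dup = build_enredo(bs)
    cycles = _enredo_cycles(m, dup.genome, max_edges_per_cycle, max_cycles)
    if max_total_length is not None:
        cycles = [c for c in cycles if c.total_length < max_total_length]
    return cycles


def classify_cycle_orientation(
    c: GenomeAlignmentCycle, genome_orientation: Mapping[str, str] | None = None
) -> str:
    """Classify by adjacency-edge direction under the chosen genome
    orientations: 'whirl' if all edges follow the traversal, 'bulge' for
    two opposing runs, 'composite' for more.

    Flipping a genome reverses its adjacency edges, so the outcome depends
    on ``genome_orientation`` — unlike the path count, which does not.
    """
    signs = []
    for sign, g in zip(c.signs, c.genomes):
        flip = genome_orientation is not None and genome_orientation.get(g, "+") == "-"
        signs.append(-sign if flip else sign)
    if len(set(signs)) == 1:
        return "whirl"
    changes = sum(
        1 for i in range(len(signs)) if signs[i] != signs[(i + 1) % len(signs)]
    )
    return "bulge" if changes == 2 else "composite"


def count_cycle_paths(c: GenomeAlignmentCycle, bs: BlockSet) -> int:
    """Number of distinct maximal colinear paths among the cycle's blocks
    (flanking blocks count through their paths).  Invariant under genome
    re-orientation."""
    paths = maximal_colinear_paths(bs)
    owner = path_of_block(paths)
    return len({owner[b] for b in c.blocks})


def detect_palindromes(m: EnredoModel) -> set[Block]:
    """Blocks with an inverted tandem duplication: a self-adjacency joining
    one end to itself (head-head or tail-tail).  Direct tandem repeats
    (head-tail self-adjacencies) are not reported."""
    bs = recover_blocks_en(m)
    out: set[Block] = set()
    for b in bs.blocks:
        for ac in adjacencies_between(b, b, bs):
            if ac.block1_end == ac.block2_end:
                out.add(b)
    return out


_VISIBILITY: dict[tuple[str, str], str] = {
    ("colinear_path", "alignment"): "needs_labels",
    ("colinear_path", "abruijn"): "needs_labels",
    ("colinear_path", "enredo"): "visible",
    ("colinear_path", "cactus"): "needs_labels",
    ("visiting_block", "alignment"): "visible",
    ("visiting_block", "abruijn"): "needs_labels",
    ("visiting_block", "enredo"): "needs_labels",
    ("visiting_block", "cactus"): "needs_labels",
    ("cycle", "alignment"): "needs_labels",
    ("cycle", "abruijn"): "needs_labels",
    ("cycle", "enredo"): "visible",
    ("cycle", "cactus"): "needs_labels",
    ("palindrome", "alignment"): "needs_labels",
    ("palindrome", "abruijn"): "needs_labels",
    ("palindrome", "enredo"): "visible",
    ("palindrome", "cactus"): "needs_labels",
    ("chain", "alignment"): "needs_labels",
    ("chain", "abruijn"): "needs_labels",
    ("chain", "enredo"): "visible",
    ("chain", "cactus"): "visible",
    ("group", "alignment"): "needs_labels",
    ("group", "abruijn"): "needs_labels",
    ("group", "enredo"): "visible",
    ("group", "cactus"): "needs_labels",
}


def visibility(substructure_kind: str, graph_kind: str) -> str:
    """Whether a substructure class is recognisable in a graph *structure*
    without label information.  No single graph reveals all of them."""
    try:
        return _VISIBILITY[(substructure_kind, graph_kind)]
    except KeyError:
        raise ValueError(
            f"unknown combination: {substructure_kind!r} / {graph_kind!r}"
        ) from None
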