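"""Structure transformations among the four graph representations.

Three directions succeed on the structure alone (alignment -> A-Bruijn,
Enredo -> A-Bruijn, Enredo -> cactus): they only ever discard information.
The three opposite directions are ambiguous and require a sparse labeling:
duplication ranks for A-Bruijn -> alignment, orientation bit pairs for
A-Bruijn -> Enredo, and the per-segment order/orientation labeling for
cactus -> Enredo.  :func:`enumerate_consistent` makes the ambiguity
arguments mechanical by enumerating, within a size cap, every target
structure consistent with a source structure (and optional partial labels),
up to type-preserving isomorphism.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Any, Iterable, Mapping, Sequence

from .abruijn import ABruijnStructure, DupLabels
from .alignment_graph import AlignmentGraphStructure
from .cactus import (
    AdjLabels,
    CactusStructure,
    build_precursor,
    collapse_bridge_trees,
    merge_3ec,
)
from .enredo import EnredoStructure
from .iso import isomorphic, structure_hash

__all__ = [
    "ag_to_ab",
    "ab_to_ag",
    "ab_to_en",
    "en_to_ab",
    "en_to_ca",
    "ca_to_en",
    "AmbiguousTransformError",
    "enumerate_threadings",
    "enumerate_consistent",
]

DEFAULT_MAX_BLOCKS = 12
DEFAULT_MAX_EDGES = 30


class AmbiguousTransformError(ValueError):
    """A transformation was attempted without the sparse labeling that
    resolves its ambiguity."""

    def __init__(self, direction: str, labeling: str):
        super().__init__(
            f"transformation {direction} is ambiguous on structures alone;"
            f" supply the {labeling} labeling"
        )
        self.labeling = labeling


def ag_to_ab(ag: AlignmentGraphStructure) -> ABruijnStructure:
    """Contract every block-edge connected component to one vertex.

    Needs no labels: the many-to-one vertex mapping is determined by the
    components.
    """
    comps = ag.block_components()
    vmap = {v: f"a{i}" for i, comp in enumerate(comps) for v in comp}
    edges = {
        f"e{k}": (vmap[u], vmap[v])
        for k, (u, v) in enumerate(sorted(ag.adjacency_edges), start=1)
    }
    return ABruijnStructure(frozenset(vmap.values()), edges)


def ab_to_ag(
    ab: ABruijnStructure, dup: DupLabels | None
) -> AlignmentGraphStructure:
    """Thread the genomes through the A-Bruijn structure, materialising one
    alignment vertex per visit.  Refused without duplication labels: with
    duplications the structure admits several threadings."""
    if dup is None:
        raise AmbiguousTransformError("abruijn -> alignment", "dup")
    mapping: dict[str, list[str]] = {v: [] for v in ab.vertices}
    vertices: set[str] = set()
    adjacency: set[tuple[str, str]] = set()
    block_edges: set[frozenset[str]] = set()
    counter = itertools.count()

    def materialise(ab_vertex: str) -> str:
        new = f"x{next(counter)}"
        vertices.add(new)
        for prev in mapping[ab_vertex]:
            block_edges.add(frozenset((prev, new)))
        mapping[ab_vertex].append(new)
        return new

    for g in sorted(set(dup.genome.values())):
        prev_vertex: str | None = None
        prev_target: str | None = None
        for eid in dup.edges_of_genome(g):
            if eid not in ab.edges:
                raise ValueError(f"duplication label on unknown edge {eid}")
            u, v = ab.edges[eid]
            if prev_vertex is None:
                prev_vertex = materialise(u)
            elif u != prev_target:
                raise ValueError(
                    "duplication labels do not chain through the edges of"
                    f" genome {g!r}"
                )
            cur = materialise(v)
            adjacency.add((prev_vertex, cur))
            prev_vertex, prev_target = cur, v
    # vertices never visited hold single-segment genomes only; they still
    # appear as isolated alignment vertices
    for v in sorted(ab.vertices):
        if not mapping[v]:
            materialise(v)
    return AlignmentGraphStructure(
        frozenset(vertices), frozenset(adjacency), frozenset(block_edges)
    )


def ab_to_en(
    ab: ABruijnStructure, inv: Mapping[str, tuple[str, str]] | None
) -> EnredoStructure:
    """Expand each vertex into a block edge with head and tail; attach each
    adjacency edge according to its orientation bit pair.  Refused without
    the bits: inversions are invisible in the A-Bruijn structure."""
    if inv is None:
        raise AmbiguousTransformError("abruijn -> enredo", "inv")
    vertices: set[str] = set()
    block_edges: set[frozenset[str]] = set()
    for v in ab.vertices:
        t, h = f"{v}.t", f"{v}.h"
        vertices.update((t, h))
        block_edges.add(frozenset((t, h)))
    adjacency: dict[str, tuple[str, str]] = {}
    for eid, (u, v) in ab.edges.items():
        if eid not in inv:
            raise AmbiguousTransformError("abruijn -> enredo", "inv")
        bit_u, bit_v = inv[eid]
        src = f"{u}.h" if bit_u == "+" else f"{u}.t"
        dst = f"{v}.t" if bit_v == "+" else f"{v}.h"
        adjacency[eid] = (src, dst)
    return EnredoStructure(
        frozenset(vertices), frozenset(block_edges), adjacency
    )


def en_to_ab(en: EnredoStructure) -> ABruijnStructure:
    """Contract each block edge to a vertex, keeping adjacency edge
    directions.  Label-free; the inversion information held by the
    two-vertex representation is lost."""
    vmap: dict[str, str] = {}
    for i, be in enumerate(sorted(en.block_edges, key=sorted)):
        for v in be:
            vmap[v] = f"a{i}"
    edges = {
        eid: (vmap[u], vmap[v]) for eid, (u, v) in en.adjacency_edges.items()
    }
    return ABruijnStructure(frozenset(vmap.values()), edges)


def en_to_ca(
    en: EnredoStructure, terminal_vertices: Iterable[str] | None = None
) -> CactusStructure:
    """The three cactus construction steps, label-free."""
    pre, _, _ = build_precursor(en, terminal_vertices)
    merged, _ = merge_3ec(pre)
    final, _ = collapse_bridge_trees(merged)
    return final


def ca_to_en(ca: CactusStructure, adj: AdjLabels | None) -> EnredoStructure:
    """Thread the genomes through the cactus structure using the
    orientation/order labeling and rebuild the Enredo structure.  Refused
    without the labeling: a cactus vertex hides which adjacencies it holds.
    """
    if adj is None:
        raise AmbiguousTransformError("cactus -> enredo", "adj")
    entries: list[tuple[int, str, str]] = []
    for eid, lst in adj.entries.items():
        if eid not in ca.edges:
            raise ValueError(f"adjacency label on unknown edge {eid}")
        for bit, n in lst:
            entries.append((n, bit, eid))
    numbers = [n for n, _, _ in entries]
    if len(set(numbers)) != len(numbers):
        raise ValueError("segment numbers must impose a strict total order")
    entries.sort()
    vertices: set[str] = set()
    block_edges: set[frozenset[str]] = set()
    adjacency: dict[str, tuple[str, str]] = {}
    ends: dict[str, tuple[str, str]] = {}  # cactus edge -> (tail, head)

    def ensure(eid: str) -> tuple[str, str]:
        if eid not in ends:
            t, h = f"{eid}.t", f"{eid}.h"
            vertices.update((t, h))
            block_edges.add(frozenset((t, h)))
            ends[eid] = (t, h)
        return ends[eid]

    cur = ca.origin
    prev_exit: str | None = None
    prev_n: int | None = None
    for n, bit, eid in entries:
        u, w = ca.edges[eid]
        fresh_genome = prev_n is None or n != prev_n + 1
        here = ca.origin if fresh_genome else cur
        if here not in (u, w):
            raise ValueError(
                f"labels are not threadable: edge {eid} is not incident to"
                f" the current vertex {here}"
            )
        t, h = ensure(eid)
        entry, exit_ = (t, h) if bit == "+" else (h, t)
        if not fresh_genome:
            assert prev_exit is not None
            adjacency[f"a{n}"] = (prev_exit, entry)
        cur = w if here == u else u
        prev_exit, prev_n = exit_, n
    if set(ends) != set(ca.edges):
        missing = sorted(set(ca.edges) - set(ends))
        raise ValueError(f"edges never threaded: {missing}")
    return EnredoStructure(
        frozenset(vertices), frozenset(block_edges), adjacency
    )


# ---------------------------------------------------------------------------
# brute-force enumeration of consistent target structures


def _check_caps(
    n_vertices: int, n_edges: int, max_blocks: int, max_edges: int
) -> None:
    if n_vertices > max_blocks or n_edges > max_edges:
        raise ValueError(
            "structure too large for exhaustive enumeration"
            f" ({n_vertices} blocks / {n_edges} edges;"
            f" caps {max_blocks} / {max_edges})"
        )


def _walk_decompositions(
    ab: ABruijnStructure, n_walks: int
) -> list[tuple[tuple[str, ...], ...]]:
    """All partitions of the edge multiset into ``n_walks`` nonempty
    directed trails (edge-id sequences); duplicates merged."""
    results: set[tuple[tuple[str, ...], ...]] = set()

    def rec(remaining: frozenset, walks: tuple, open_walk: tuple, end: str | None):
        if open_walk:
            # close the open walk ...
            rec(remaining, walks + (open_walk,), (), None)
            # ... or extend it
            for eid in sorted(remaining):
                u, v = ab.edges[eid]
                if u == end:
                    rec(remaining - {eid}, walks, open_walk + (eid,), v)
            return
        if not remaining:
            if len(walks) == n_walks:
                results.add(tuple(sorted(walks)))
            return
        if len(walks) >= n_walks:
            return
        for eid in sorted(remaining):
            u, v = ab.edges[eid]
            rec(remaining - {eid}, walks, (eid,), v)

    rec(frozenset(ab.edges), (), (), None)
    return sorted(results)


def _walk_vertices(ab: ABruijnStructure, walk: Sequence[str]) -> list[str]:
    u0, _ = ab.edges[walk[0]]
    return [u0] + [ab.edges[e][1] for e in walk]


def enumerate_threadings(
    ab: ABruijnStructure,
    n_genomes: int = 1,
    max_blocks: int = DEFAULT_MAX_BLOCKS,
    max_edges: int = DEFAULT_MAX_EDGES,
) -> set[tuple[tuple[str, ...], ...]]:
    """All ways to thread ``n_genomes`` genomes through the structure so
    that every adjacency edge is used exactly once.

    Returns, per threading, the sorted tuple of the genomes' block-order
    (vertex) sequences.  More than one outcome witnesses threading
    ambiguity; duplications are the only possible cause.  Genomes of a
    single segment contribute no edges and are not modelled here.
    """
    _check_caps(len(ab.vertices), len(ab.edges), max_blocks, max_edges)
    out: set[tuple[tuple[str, ...], ...]] = set()
    for decomp in _walk_decompositions(ab, n_genomes):
        out.add(tuple(sorted(tuple(_walk_vertices(ab, w)) for w in decomp)))
    return out


def _occurrences(
    ab: ABruijnStructure, decomp: Sequence[Sequence[str]]
) -> list[tuple[int, int, str]]:
    occs = []
    for wi, walk in enumerate(decomp):
        for pos, v in enumerate(_walk_vertices(ab, walk)):
            occs.append((wi, pos, v))
    return occs


def _bit_assignments(
    occurrences: Sequence[tuple[int, int, str]],
    partial: Mapping[str, Sequence[str]] | None,
):
    """Yield orientation bit assignments per occurrence, filtered by the
    per-vertex bit multiset constraints ('*' entries are free)."""
    for bits in itertools.product("+-", repeat=len(occurrences)):
        assignment = dict(zip(occurrences, bits))
        if partial is not None:
            per_vertex: dict[str, list[str]] = {}
            for (wi, pos, v), bit in assignment.items():
                per_vertex.setdefault(v, []).append(bit)
            ok = True
            for v, pattern in partial.items():
                got = Counter(per_vertex.get(v, []))
                want = Counter(b for b in pattern if b != "*")
                free = sum(1 for b in pattern if b == "*")
                if (
                    sum(got.values()) != len(pattern)
                    or (want - got)
                    or sum((got - want).values()) != free
                ):
                    ok = False
                    break
            if not ok:
                continue
        yield assignment


def _enredo_from_walks(
    ab: ABruijnStructure,
    decomp: Sequence[Sequence[str]],
    bits: Mapping[tuple[int, int, str], str],
) -> EnredoStructure:
    vertices: set[str] = set()
    block_edges: set[frozenset[str]] = set()
    for v in ab.vertices:
        t, h = f"{v}.t", f"{v}.h"
        vertices.update((t, h))
        block_edges.add(frozenset((t, h)))
    adjacency: dict[str, tuple[str, str]] = {}
    for wi, walk in enumerate(decomp):
        vs = _walk_vertices(ab, walk)
        for pos in range(len(vs) - 1):
            b1 = bits[(wi, pos, vs[pos])]
            b2 = bits[(wi, pos + 1, vs[pos + 1])]
            src = f"{vs[pos]}.h" if b1 == "+" else f"{vs[pos]}.t"
            dst = f"{vs[pos + 1]}.t" if b2 == "+" else f"{vs[pos + 1]}.h"
            adjacency[f"w{wi}p{pos}"] = (src, dst)
    return EnredoStructure(
        frozenset(vertices), frozenset(block_edges), adjacency
    )


def _alignment_from_walks(
    ab: ABruijnStructure, decomp: Sequence[Sequence[str]]
) -> AlignmentGraphStructure:
    vertices: set[str] = set()
    adjacency: set[tuple[str, str]] = set()
    members: dict[str, list[str]] = {v: [] for v in ab.vertices}
    counter = itertools.count()
    for walk in decomp:
        prev = None
        for v in _walk_vertices(ab, walk):
            new = f"x{next(counter)}"
            vertices.add(new)
            members[v].append(new)
            if prev is not None:
                adjacency.add((prev, new))
            prev = new
    block_edges = {
        frozenset(pair)
        for group in members.values()
        for pair in itertools.combinations(group, 2)
    }
    for v, group in members.items():
        if not group:
            vertices.add(f"x{next(counter)}")
    return AlignmentGraphStructure(
        frozenset(vertices), frozenset(adjacency), frozenset(block_edges)
    )


def _dedupe(structures: Iterable[Any]) -> list[Any]:
    buckets: dict[str, list[Any]] = {}
    out: list[Any] = []
    for s in structures:
        h = structure_hash(s)
        group = buckets.setdefault(h, [])
        if not any(isomorphic(s, other) for other in group):
            group.append(s)
            out.append(s)
    return out


def _cactus_walks(
    ca: CactusStructure,
    n_genomes: int,
    max_traversals: int,
) -> list[EnredoStructure]:
    """Enumerate Enredo structures arising from sets of ``n_genomes``
    origin-to-origin walks over the cactus structure, with at most
    ``max_traversals`` edge traversals in total and every edge traversed at
    least once."""
    ends: dict[str, tuple[str, str]] = {
        eid: (f"{eid}.t", f"{eid}.h") for eid in ca.edges
    }
    vertices = frozenset(v for pair in ends.values() for v in pair)
    block_edges = frozenset(frozenset(pair) for pair in ends.values())
    results: list[EnredoStructure] = []

    def build(walks: Sequence[Sequence[tuple[str, str]]]) -> EnredoStructure:
        adjacency: dict[str, tuple[str, str]] = {}
        for wi, walk in enumerate(walks):
            prev_exit = None
            for pos, (eid, bit) in enumerate(walk):
                t, h = ends[eid]
                entry, exit_ = (t, h) if bit == "+" else (h, t)
                if prev_exit is not None:
                    adjacency[f"w{wi}p{pos}"] = (prev_exit, entry)
                prev_exit = exit_
        return EnredoStructure(vertices, block_edges, adjacency)

    incident = {
        v: sorted(
            eid for eid, (u, w) in ca.edges.items() if v in (u, w)
        )
        for v in ca.vertices
    }

    def other_end(eid: str, v: str) -> str:
        u, w = ca.edges[eid]
        return w if v == u else u

    all_walks: list[list[tuple[str, str]]] = []

    def walk_rec(cur: str, walk: list[tuple[str, str]], budget: int):
        if cur == ca.origin and walk:
            all_walks.append(list(walk))
        if budget == 0:
            return
        for eid in incident[cur]:
            for bit in "+-":
                walk.append((eid, bit))
                walk_rec(other_end(eid, cur), walk, budget - 1)
                walk.pop()

    walk_rec(ca.origin, [], max_traversals)
    for combo in itertools.combinations_with_replacement(
        range(len(all_walks)), n_genomes
    ):
        walks = [all_walks[i] for i in combo]
        if sum(len(w) for w in walks) > max_traversals:
            continue
        used = Counter(eid for w in walks for eid, _ in w)
        if set(used) != set(ca.edges):
            continue
        results.append(build(walks))
    return results


def enumerate_consistent(
    source: Any,
    target_kind: str,
    partial_labels: Mapping[str, Sequence[str]] | None = None,
    n_genomes: int = 1,
    max_blocks: int = DEFAULT_MAX_BLOCKS,
    max_edges: int = DEFAULT_MAX_EDGES,
    max_traversals: int = 8,
) -> list[Any]:
    """Enumerate, up to type-preserving isomorphism, the target structures
    whose label-free back-transformation equals ``source``.

    Supported directions: A-Bruijn -> alignment (unknown: the genome
    threading), A-Bruijn -> enredo (unknowns: threading and per-occurrence
    orientation bits; ``partial_labels`` optionally constrains the bit
    multiset per vertex, '*' marking free entries), cactus -> enredo
    (unknowns: the genome walks; bounded by ``max_traversals``), and the
    unambiguous alignment -> abruijn.  Enumeration is exponential and
    guarded by size caps.
    """
    if isinstance(source, AlignmentGraphStructure) and target_kind == "abruijn":
        return [ag_to_ab(source)]
    if isinstance(source, ABruijnStructure):
        _check_caps(len(source.vertices), len(source.edges), max_blocks, max_edges)
        decomps = _walk_decompositions(source, n_genomes)
        if target_kind == "alignment":
            return _dedupe(_alignment_from_walks(source, d) for d in decomps)
        if target_kind == "enredo":
            candidates = []
            for d in decomps:
                occs = _occurrences(source, d)
                for bits in _bit_assignments(occs, partial_labels):
                    candidates.append(_enredo_from_walks(source, d, bits))
            return _dedupe(candidates)
    if isinstance(source, CactusStructure) and target_kind == "enredo":
        _check_caps(len(source.vertices), len(source.edges), max_blocks, max_edges)
        return _dedupe(_cactus_walks(source, n_genomes, max_traversals))
    if isinstance(source, EnredoStructure) and target_kind == "abruijn":
        return [en_to_ab(source)]
    raise ValueError(
        f"unsupported enumeration: {type(source).__name__} -> {target_kind}"
    )
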