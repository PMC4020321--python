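"""Cactus graph: vertices are sets of adjacencies (plus one origin), edges
are blocks.

Constructed from an Enredo structure in three steps — adjacency-component
contraction, merging of 3-edge-connected vertex sets, and collapsing of
bridge trees — after which every edge lies on at most one simple cycle (the
cactus property) and, counting each block with multiplicity equal to its
size, the multigraph is Eulerian.  Simple cycles are *chains*; the
adjacency components that were contracted in the first step are *groups*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .core import Block, BlockSet
from .enredo import EnredoModel, EnredoStructure

__all__ = [
    "CactusStructure",
    "CactusModel",
    "AdjLabels",
    "ORIGIN",
    "build_precursor",
    "merge_3ec",
    "collapse_bridge_trees",
    "build_cactus",
    "verify_cactus",
    "verify_eulerian",
    "chains",
    "groups",
    "terminal_vertices_of_model",
    "adj_labels_of",
]

ORIGIN = "origin"


@dataclass(frozen=True)
class CactusStructure:
    """Undirected multigraph with individually identified edges and one
    distinguished origin vertex; self-loops allowed."""

    vertices: frozenset[str]
    origin: str
    edges: Mapping[str, tuple[str, str]]  # edge id -> unordered endpoint pair

    def __post_init__(self) -> None:
        if self.origin not in self.vertices:
            raise ValueError("origin must be a vertex")

    def degree(self, v: str, multiplicity: Mapping[str, int] | None = None) -> int:
        d = 0
        for e, (u, w) in self.edges.items():
            m = 1 if multiplicity is None else multiplicity[e]
            d += ((u == v) + (w == v)) * m
        return d


@dataclass(frozen=True)
class AdjLabels:
    """Per-edge lists of (orientation bit, number), one entry per segment of
    the edge's block.

    The numbers impose a strict total order on all genome segments (left to
    right, genomes in their total order).  Numbering within one genome is
    consecutive; a gap of one marks each genome boundary, which is what lets
    threading restart at the origin.
    """

    entries: Mapping[str, tuple[tuple[str, int], ...]]


@dataclass(frozen=True)
class CactusModel:
    structure: CactusStructure
    labels: Mapping[str, Block]  # edge id -> block
    adj_labels: AdjLabels
    genome_lengths: Mapping[str, int]
    enredo: EnredoModel  # the method keeps the Enredo-like graph alongside
    vertex_map: Mapping[str, str] = None  # type: ignore[assignment]
    # Enredo vertex -> cactus vertex, composed across the three steps

    def __post_init__(self) -> None:
        if self.vertex_map is None:
            object.__setattr__(self, "vertex_map", {})


def build_precursor(
    en: EnredoStructure, terminal_vertices: Iterable[str] | None = None
) -> tuple[CactusStructure, dict[str, str], dict[frozenset, str]]:
    """Step one: contract adjacency-edge connected components.

    Returns the precursor structure, the Enredo-vertex -> cactus-vertex
    mapping, and the block-edge -> cactus-edge mapping.  Components holding
    a genome terminus all collapse into the single origin vertex; at
    structure level the termini default to the vertices without incident
    adjacency edges.
    """
    g = nx.Graph()
    g.add_nodes_from(en.vertices)
    for u, w in en.adjacency_edges.values():
        g.add_edge(u, w)
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=tuple)
    if terminal_vertices is None:
        terminal = {
            v for v in en.vertices if en.adjacency_degree(v) == 0
        }
    else:
        terminal = set(terminal_vertices)
    vmap: dict[str, str] = {}
    names: list[str] = []
    k = 0
    for comp in comps:
        if terminal.intersection(comp) or not en.vertices:
            name = ORIGIN
        else:
            name = f"v{k}"
            k += 1
        for v in comp:
            vmap[v] = name
        names.append(name)
    vertices = set(vmap.values()) | {ORIGIN}
    edges: dict[str, tuple[str, str]] = {}
    emap: dict[frozenset, str] = {}
    for i, be in enumerate(sorted(en.block_edges, key=sorted)):
        u, w = sorted(be)
        eid = f"c{i}"
        edges[eid] = (vmap[u], vmap[w])
        emap[be] = eid
    return CactusStructure(frozenset(vertices), ORIGIN, edges), vmap, emap


def _nx_multigraph(c: CactusStructure) -> nx.MultiGraph:
    g = nx.MultiGraph()
    g.add_nodes_from(c.vertices)
    for eid, (u, w) in c.edges.items():
        g.add_edge(u, w, key=eid)
    return g


def _three_edge_connected_classes(c: CactusStructure) -> list[set[str]]:
    """Vertex classes under 3-edge-connectivity, by repeated min cut.

    Desk-scale quadratic max-flow; a linear-time algorithm would do the
    same merging.
    """
    g = nx.Graph()
    g.add_nodes_from(c.vertices)
    for u, w in c.edges.values():
        if u == w:
            continue  # self-loops never contribute to connectivity
        if g.has_edge(u, w):
            g[u][w]["capacity"] += 1
        else:
            g.add_edge(u, w, capacity=1)
    parent = {v: v for v in c.vertices}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, w in itertools.combinations(sorted(c.vertices), 2):
        if find(u) == find(w):
            continue
        if not g.has_node(u) or not g.has_node(w):
            continue
        if not nx.has_path(g, u, w):
            continue
        flow = nx.maximum_flow_value(g, u, w)
        if flow >= 3:
            parent[find(u)] = find(w)
    classes: dict[str, set[str]] = {}
    for v in c.vertices:
        classes.setdefault(find(v), set()).add(v)
    return sorted(classes.values(), key=sorted)


def _quotient(
    c: CactusStructure, classes: list[set[str]]
) -> tuple[CactusStructure, dict[str, str]]:
    vmap: dict[str, str] = {}
    names: set[str] = set()
    k = 0
    for cl in classes:
        if c.origin in cl:
            name = c.origin
        elif len(cl) == 1:
            name = next(iter(cl))
        else:
            name = f"m{k}"
            while name in c.vertices:
                k += 1
                name = f"m{k}"
            k += 1
        names.add(name)
        for v in cl:
            vmap[v] = name
    edges = {
        eid: (vmap[u], vmap[w]) for eid, (u, w) in c.edges.items()
    }
    return CactusStructure(frozenset(names), c.origin, edges), vmap


def merge_3ec(c: CactusStructure) -> tuple[CactusStructure, dict[str, str]]:
    """Step two: merge every 3-edge-connected set of vertices into one."""
    return _quotient(c, _three_edge_connected_classes(c))


def _multigraph_bridges(c: CactusStructure) -> set[str]:
    """Edges whose removal disconnects the multigraph (never self-loops or
    members of parallel bundles)."""
    simple = nx.Graph()
    simple.add_nodes_from(c.vertices)
    count: dict[frozenset, int] = {}
    for u, w in c.edges.values():
        if u == w:
            continue
        count[frozenset((u, w))] = count.get(frozenset((u, w)), 0) + 1
        simple.add_edge(u, w)
    bridge_pairs = {frozenset(e) for e in nx.bridges(simple)}
    return {
        eid
        for eid, (u, w) in c.edges.items()
        if u != w
        and frozenset((u, w)) in bridge_pairs
        and count[frozenset((u, w))] == 1
    }


def collapse_bridge_trees(
    c: CactusStructure,
) -> tuple[CactusStructure, dict[str, str]]:
    """Step three: collapse every connected component formed only by bridge
    edges (a tree) into a single vertex; its edges become self-loops."""
    bridges = _multigraph_bridges(c)
    forest = nx.Graph()
    forest.add_nodes_from(c.vertices)
    for eid in bridges:
        u, w = c.edges[eid]
        forest.add_edge(u, w)
    classes = [set(comp) for comp in nx.connected_components(forest)]
    return _quotient(c, sorted(classes, key=sorted))


def terminal_vertices_of_model(m: EnredoModel) -> set[str]:
    """Enredo vertices holding at least one genome terminus."""
    bs = _recover(m)
    vertex_of_end: dict[tuple[str, str], str] = {}
    for e, b in m.labels.items():
        h = m.head_vertex[e]
        (t,) = set(e) - {h}
        vertex_of_end[(str(b.id), "head")] = h
        vertex_of_end[(str(b.id), "tail")] = t
    terminal: set[str] = set()
    for g in bs.genomes:
        order = bs.segments_in_order(g)
        if not order:
            continue
        s_first, b_first = order[0]
        s_last, b_last = order[-1]
        # genome enters its first segment on the left, leaves the last on
        # the right; a forward segment enters at the tail and exits at the
        # head, a reverse one the other way around
        terminal.add(
            vertex_of_end[
                (str(b_first.id), "tail" if s_first.is_forward else "head")
            ]
        )
        terminal.add(
            vertex_of_end[
                (str(b_last.id), "head" if s_last.is_forward else "tail")
            ]
        )
    return terminal


def _recover(m: EnredoModel) -> BlockSet:
    from .enredo import recover_blocks_en

    return recover_blocks_en(m)


def adj_labels_of(m: EnredoModel, emap: Mapping[frozenset, str]) -> AdjLabels:
    """Orientation-bit/segment-number labels for the cactus edges.

    Segments are numbered left to right, genomes in lexicographic order;
    numbering is consecutive within a genome with a gap of one between
    genomes.
    """
    bs = _recover(m)
    number: dict = {}
    n = 0
    for g in bs.genomes:
        n += 1  # gap marking the genome boundary
        for s, _b in bs.segments_in_order(g):
            n += 1
            number[s] = n
    entries: dict[str, list[tuple[str, int]]] = {}
    block_of_edge = {emap[e]: b for e, b in m.labels.items()}
    for eid, b in block_of_edge.items():
        lst = [(s.orientation, number[s]) for s in b.canonical.segments]
        lst.sort(key=lambda t: t[1])
        entries[eid] = lst
    return AdjLabels({e: tuple(v) for e, v in sorted(entries.items())})


def build_cactus(en: EnredoModel) -> CactusModel:
    """Three-step construction with label transfer."""
    terminal = terminal_vertices_of_model(en)
    pre, vmap, emap = build_precursor(en.structure, terminal)
    merged, vmap2 = merge_3ec(pre)
    final, vmap3 = collapse_bridge_trees(merged)
    labels = {emap[e]: b for e, b in en.labels.items()}
    adj = adj_labels_of(en, emap)
    composed = {v: vmap3[vmap2[vmap[v]]] for v in en.structure.vertices}
    return CactusModel(
        final, labels, adj, dict(en.genome_lengths), en, composed
    )


def _cycle_components(c: CactusStructure) -> tuple[bool, list[frozenset[str]]]:
    """Decompose into simple-cycle edge sets.

    Returns (is_cactus, cycles): each biconnected component of the
    multigraph must be a single edge or a simple cycle; self-loops count as
    one-edge cycles.  Biconnected components are computed on a subdivision
    of the multigraph (a midpoint node per edge makes it simple without
    changing the cycle structure).
    """
    g = nx.Graph()
    g.add_nodes_from(c.vertices)
    loops: list[str] = []
    for eid, (u, w) in c.edges.items():
        if u == w:
            loops.append(eid)
            continue
        mid = ("mid", eid)
        g.add_node(mid)
        g.add_edge(u, mid)
        g.add_edge(mid, w)
    cycles = [frozenset((eid,)) for eid in loops]
    ok = True
    for comp_edges in nx.biconnected_component_edges(g):
        nodes = {v for e in comp_edges for v in e}
        members = frozenset(
            n[1] for n in nodes if isinstance(n, tuple) and n[0] == "mid"
        )
        if len(members) <= 1:
            continue  # a bridge
        # a simple cycle of k edges subdivides into a 2k-cycle
        if len(comp_edges) == len(nodes) and len(comp_edges) == 2 * len(members):
            cycles.append(members)
        else:
            ok = False
    return ok, cycles


def verify_cactus(c: CactusStructure) -> bool:
    """True iff every edge lies on at most one simple cycle, i.e. every
    biconnected component of the multigraph is a single edge, a self-loop,
    or a simple cycle."""
    ok, _ = _cycle_components(c)
    return ok


def verify_eulerian(m: CactusModel) -> bool:
    """True iff, counting each edge with multiplicity equal to its block's
    size, the multigraph is connected and every vertex has even degree.
    Only under this counting does the Eulerian circuit traverse every genome
    segment exactly once."""
    c = m.structure
    mult = {e: m.labels[e].size for e in c.edges}
    for v in c.vertices:
        d = 0
        for e, (u, w) in c.edges.items():
            d += ((u == v) + (w == v)) * mult[e]
        if d % 2:
            return False
    g = _nx_multigraph(c)
    used = {v for uv in c.edges.values() for v in uv}
    if not used:
        return True
    return nx.is_connected(g.subgraph(used))


def chains(c: CactusStructure) -> set[frozenset[str]]:
    """The chains: edge sets of the simple cycles.  Pairwise edge-disjoint
    by the cactus property; a self-loop forms a chain of one block."""
    ok, cycles = _cycle_components(c)
    if not ok:
        raise ValueError("structure is not a cactus graph")
    return set(cycles)


def groups(en: EnredoStructure) -> set[frozenset[str]]:
    """Cactus groups: adjacency-edge connected components of the Enredo
    graph, as sets of adjacency edge ids.  Groups refine cactus vertices."""
    g = nx.Graph()
    for eid, (u, w) in en.adjacency_edges.items():
        g.add_edge(u, w)
    out: set[frozenset[str]] = set()
    for comp in nx.connected_components(g):
        out.add(
            frozenset(
                eid
                for eid, (u, w) in en.adjacency_edges.items()
                if u in comp or w in comp
            )
        )
    return out
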