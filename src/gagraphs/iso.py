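"""Type-preserving isomorphism between graph structures.

Two structures of the same kind are compared up to relabeling of vertices.
Edge types (adjacency vs block), adjacency edge direction, and the cactus
origin are invariants; block-edge pairing in Enredo structures is preserved
because block edges are part of the matched edge set.
"""

from __future__ import annotations

from typing import Any

import networkx as nx
from networkx.algorithms import isomorphism as nxiso

from .abruijn import ABruijnStructure
from .alignment_graph import AlignmentGraphStructure
from .cactus import CactusStructure
from .enredo import EnredoStructure

__all__ = ["to_nx", "isomorphic", "structure_hash"]


def to_nx(structure: Any) -> nx.MultiDiGraph | nx.MultiGraph:
    """Canonical networkx form: directed multigraph with 'kind'-typed edges
    (block edges as arc pairs) for the mixed graphs, undirected multigraph
    with an origin-marked node for cactus structures."""
    if isinstance(structure, AlignmentGraphStructure):
        g = nx.MultiDiGraph()
        g.add_nodes_from(structure.vertices, kind="v")
        for u, v in structure.adjacency_edges:
            g.add_edge(u, v, kind="adj")
        for e in structure.block_edges:
            u, v = sorted(e)
            g.add_edge(u, v, kind="block")
            g.add_edge(v, u, kind="block")
        return g
    if isinstance(structure, ABruijnStructure):
        g = nx.MultiDiGraph()
        g.add_nodes_from(structure.vertices, kind="v")
        for u, v in structure.edges.values():
            g.add_edge(u, v, kind="adj")
        return g
    if isinstance(structure, EnredoStructure):
        g = nx.MultiDiGraph()
        g.add_nodes_from(structure.vertices, kind="v")
        for e in structure.block_edges:
            u, v = sorted(e)
            g.add_edge(u, v, kind="block")
            g.add_edge(v, u, kind="block")
        for u, v in structure.adjacency_edges.values():
            g.add_edge(u, v, kind="adj")
        return g
    if isinstance(structure, CactusStructure):
        g = nx.MultiGraph()
        for v in structure.vertices:
            g.add_node(v, kind="origin" if v == structure.origin else "v")
        for u, v in structure.edges.values():
            g.add_edge(u, v, kind="block")
        return g
    raise TypeError(f"not a graph structure: {type(structure).__name__}")


def isomorphic(s1: Any, s2: Any) -> bool:
    """Type-preserving isomorphism of two structures of the same kind."""
    if type(s1) is not type(s2):
        raise TypeError("cannot compare structures of different kinds")
    g1, g2 = to_nx(s1), to_nx(s2)
    nm = nxiso.categorical_node_match("kind", "v")
    em = nxiso.categorical_multiedge_match("kind", "adj")
    if g1.is_directed():
        matcher = nxiso.MultiDiGraphMatcher(g1, g2, nm, em)
    else:
        matcher = nxiso.MultiGraphMatcher(g1, g2, nm, em)
    return matcher.is_isomorphic()


def structure_hash(structure: Any) -> str:
    """Invariant fingerprint for bucketing candidates before the exact
    isomorphism check; isomorphic structures hash equal, non-isomorphic
    ones may collide.  Based on the sorted per-vertex degree profile split
    by edge kind and direction."""
    g = to_nx(structure)
    profiles = []
    for v in g.nodes:
        counts: dict[tuple[str, str], int] = {}
        if g.is_directed():
            for _, _, d in g.out_edges(v, data=True):
                key = (d["kind"], "out")
                counts[key] = counts.get(key, 0) + 1
            for _, _, d in g.in_edges(v, data=True):
                key = (d["kind"], "in")
                counts[key] = counts.get(key, 0) + 1
        else:
            for _, _, d in g.edges(v, data=True):
                key = (d["kind"], "u")
                counts[key] = counts.get(key, 0) + 1
        profiles.append(
            (g.nodes[v].get("kind", "v"), tuple(sorted(counts.items())))
        )
    return repr(sorted(profiles))
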