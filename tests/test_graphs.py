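"""Construction, labeling and recovery for the four graph representations,
plus the cactus construction steps and their structural guarantees."""

import itertools

import networkx as nx
import pytest

from gagraphs.abruijn import build_abruijn, recover_blocks_ab, thread_genome_ab
from gagraphs.alignment_graph import (
    build_alignment_graph,
    inv_labels_ag,
    recover_blocks_ag,
)
from gagraphs.cactus import (
    CactusStructure,
    build_cactus,
    build_precursor,
    chains,
    collapse_bridge_trees,
    groups,
    merge_3ec,
    terminal_vertices_of_model,
    verify_cactus,
    verify_eulerian,
)
from gagraphs.core import Block, BlockSet, Segment
from gagraphs.enredo import (
    build_enredo,
    collapse_size1_blocks,
    expand_labeled_adjacencies,
    recover_blocks_en,
)
from gagraphs.iso import isomorphic
from gagraphs.synthetic import fixture, generate

from conftest import layout_blockset, random_blockset


class TestAlignmentGraph:
    def test_letter_genome_counts(self, fig6):
        m = build_alignment_graph(fig6)
        s = m.structure
        assert len(s.vertices) == 9
        assert len(s.adjacency_edges) == 8
        # clique sizes n(n-1)/2 for block sizes 2,3,2,1,1
        assert len(s.block_edges) == 1 + 3 + 1 + 0 + 0

    def test_single_block_graph(self):
        bs = BlockSet({"g": 3}, [Block("b", [Segment("g", 0, 3)])])
        m = build_alignment_graph(bs)
        assert len(m.structure.vertices) == 1
        assert not m.structure.adjacency_edges and not m.structure.block_edges

    def test_eleven_block_fixture_components(self):
        m = build_alignment_graph(fixture("fig4"))
        assert len(m.structure.block_components()) == 11

    def test_round_trip(self, fig6):
        assert recover_blocks_ag(build_alignment_graph(fig6)) == fig6

    def test_empty_round_trip(self):
        bs = BlockSet({}, [])
        assert recover_blocks_ag(build_alignment_graph(bs)) == bs

    @pytest.mark.parametrize("seed", range(30))
    def test_random_round_trip(self, seed):
        bs = random_blockset(seed)
        assert recover_blocks_ag(build_alignment_graph(bs)) == bs

    def test_threading_reproduces_segment_order(self):
        bs = random_blockset(4)
        m = build_alignment_graph(bs)
        succ = dict(m.structure.adjacency_edges)
        starts = set(m.structure.vertices) - {
            v for _, v in m.structure.adjacency_edges
        }
        walked = []
        for v in sorted(starts):
            chain = [v]
            while chain[-1] in succ:
                chain.append(succ[chain[-1]])
            walked.append([m.labels[x] for x in chain])
        expected = [
            [s for s, _ in bs.segments_in_order(g)] for g in bs.genomes
        ]
        assert sorted(map(repr, walked)) == sorted(map(repr, expected))

    def test_orientation_labels(self):
        bs = layout_blockset(
            {"g1": [("A", "+"), ("B", "+")], "g2": [("A", "+"), ("B", "-")]}
        )
        m = build_alignment_graph(bs)
        inv = inv_labels_ag(m)
        bits = sorted(inv[v] for v in m.structure.vertices)
        assert bits == ["+", "+", "+", "-"] or bits == ["+", "+", "-", "+"] or sorted(bits) == ["+", "+", "+", "-"]

    def test_duplications_visible_as_within_genome_block_edges(self):
        bs = layout_blockset({"g1": [("A", "+"), ("B", "+"), ("A", "+")]})
        m = build_alignment_graph(bs)
        within = [
            e
            for e in m.structure.block_edges
            if len({m.labels[v].genome for v in e}) == 1
        ]
        assert within


class TestABruijn:
    def test_letter_genome_counts_and_dup_labels(self, fig6):
        m, dup, inv = build_abruijn(fig6)
        assert len(m.structure.vertices) == 5
        assert len(m.structure.edges) == 8
        assert sorted(dup.rank.values()) == list(range(1, 9))
        by_rank = {r: e for e, r in dup.rank.items()}
        assert m.structure.edges[by_rank[1]] == ("A", "B")
        assert m.structure.edges[by_rank[2]] == ("B", "D")
        assert m.structure.edges[by_rank[3]] == ("D", "A")

    def test_single_block(self):
        bs = BlockSet({"g": 3}, [Block("b", [Segment("g", 0, 3)])])
        m, dup, inv = build_abruijn(bs)
        assert len(m.structure.vertices) == 1 and not m.structure.edges

    def test_inversion_invisible_in_structure(self, fig5_pair):
        fwd, inv_bs = fig5_pair
        s1 = build_abruijn(fwd)[0].structure
        s2 = build_abruijn(inv_bs)[0].structure
        assert isomorphic(s1, s2)

    @pytest.mark.parametrize("seed", range(30))
    def test_random_round_trip(self, seed):
        bs = random_blockset(seed)
        assert recover_blocks_ab(build_abruijn(bs)[0]) == bs

    def test_threading_letter_genome(self, fig6):
        m, dup, _ = build_abruijn(fig6)
        walk = thread_genome_ab(m, dup, "g1")
        assert [v for _, v in walk] == list("ABDABCEBC")
        used = [e for e, _ in walk if e is not None]
        assert sorted(used) == sorted(dup.edges_of_genome("g1"))

    @pytest.mark.parametrize("seed", range(20))
    def test_threading_matches_generator_order(self, seed):
        r = generate(seed, p_inversion=0.3, p_duplication=0.3)
        m, dup, _ = build_abruijn(r.block_set)
        for g in r.block_set.genomes:
            walk = thread_genome_ab(m, dup, g)
            expected = [
                str(b.id) for _, b in r.block_set.segments_in_order(g)
            ]
            assert [v for _, v in walk] == expected

    def test_degree_equals_non_terminal_segments(self):
        bs = random_blockset(7)
        m, _, _ = build_abruijn(bs)
        last_of = {
            g: bs.segments_in_order(g)[-1][1] for g in bs.genomes
        }
        first_of = {
            g: bs.segments_in_order(g)[0][1] for g in bs.genomes
        }
        for v, b in m.labels.items():
            n_final = sum(
                1
                for g in bs.genomes
                if last_of[g] == b
                for s in b.segments
                if s == bs.segments_in_order(g)[-1][0]
            )
            out_deg = len(m.structure.out_edges(v))
            assert out_deg == b.size - n_final


class TestEnredo:
    def test_forward_chain(self):
        bs = layout_blockset({"g1": [("A", "+"), ("B", "+"), ("C", "+")]})
        m, dup = build_enredo(bs)
        s = m.structure
        assert len(s.vertices) == 6
        assert len(s.block_edges) == 3
        assert len(s.adjacency_edges) == 2
        for eid, (u, v) in s.adjacency_edges.items():
            assert u.endswith(".h") and v.endswith(".t")

    def test_inversions_visible(self, fig5_pair):
        fwd, inv_bs = fig5_pair
        e1, _ = build_enredo(fwd)
        e2, _ = build_enredo(inv_bs)
        assert not isomorphic(e1.structure, e2.structure)

    def test_letter_genome_dup_labels(self, fig6):
        m, dup = build_enredo(fig6)
        assert sorted(dup.rank.values()) == list(range(1, 9))
        by_rank = {r: e for e, r in dup.rank.items()}
        assert m.structure.adjacency_edges[by_rank[1]] == ("A.h", "B.t")
        assert m.structure.adjacency_edges[by_rank[2]] == ("B.h", "D.t")

    @pytest.mark.parametrize("seed", range(30))
    def test_random_round_trip(self, seed):
        bs = random_blockset(seed)
        assert recover_blocks_en(build_enredo(bs)[0]) == bs

    def test_unique_threading_with_opposite_orientations(self):
        # a block occurring once forward and once reverse complemented in a
        # genome threads unambiguously: the two traversals enter through
        # different vertices
        bs = layout_blockset(
            {"g1": [("A", "+"), ("B", "+"), ("A", "-"), ("B", "+")]}
        )
        m, _ = build_enredo(bs)
        entries = [
            v for _, v in m.structure.adjacency_edges.values()
        ]
        a_entries = [v for v in entries if v.startswith("A.")]
        assert len(set(a_entries)) == len(a_entries)

    def test_collapse_and_expand_inverse(self):
        bs = BlockSet(
            {"g1": 5, "g2": 5},
            [
                Block("A", [Segment("g1", 0, 2), Segment("g2", 0, 2)]),
                Block("x", [Segment("g1", 2, 3)]),
                Block("y", [Segment("g2", 2, 3)]),
                Block("B", [Segment("g1", 3, 5), Segment("g2", 3, 5)]),
            ],
        )
        m, _ = build_enredo(bs)
        col = collapse_size1_blocks(m)
        assert len(col.labels) == 2
        assert len(col.adjacency_segment_labels) == 2
        exp = expand_labeled_adjacencies(col)
        assert recover_blocks_en(exp) == bs
        assert isomorphic(exp.structure, m.structure)

    def test_collapse_without_size1_is_identity(self):
        m, _ = build_enredo(fixture("fig5_forward"))
        col = collapse_size1_blocks(m)
        assert col.labels == dict(m.labels)

    def test_terminal_size1_blocks_kept(self):
        bs = layout_blockset({"g1": [("x", "+"), ("A", "+")]})
        m, _ = build_enredo(bs)
        col = collapse_size1_blocks(m)
        assert len(col.labels) == 2  # nothing collapsed

    def test_expand_grows_block_count_by_labeled_edges(self):
        bs = BlockSet(
            {"g1": 5, "g2": 5},
            [
                Block("A", [Segment("g1", 0, 2), Segment("g2", 0, 2)]),
                Block("x", [Segment("g1", 2, 3)]),
                Block("y", [Segment("g2", 2, 3)]),
                Block("B", [Segment("g1", 3, 5), Segment("g2", 3, 5)]),
            ],
        )
        m, _ = build_enredo(bs)
        col = collapse_size1_blocks(m)
        n_labeled = len(col.adjacency_segment_labels)
        exp = expand_labeled_adjacencies(col)
        assert len(exp.labels) == len(col.labels) + n_labeled


def brute_force_simple_cycles(c: CactusStructure):
    """Independent oracle: every simple cycle as an edge set, found by DFS
    over a double-subdivision of the multigraph."""
    g = nx.Graph()
    g.add_nodes_from(c.vertices)
    for eid, (u, w) in c.edges.items():
        g.add_node(("m1", eid))
        g.add_node(("m2", eid))
        g.add_edge(u, ("m1", eid))
        g.add_edge(("m1", eid), ("m2", eid))
        g.add_edge(("m2", eid), w)
    out = set()
    for cyc in nx.simple_cycles(g):
        eids = frozenset(n[1] for n in cyc if isinstance(n, tuple))
        if eids:
            out.add(eids)
    return out


class TestCactus:
    def test_forward_chain_precursor_is_cycle(self):
        bs = layout_blockset({"g1": [("A", "+"), ("B", "+"), ("C", "+")]})
        m, _ = build_enredo(bs)
        pre, vmap, emap = build_precursor(
            m.structure, terminal_vertices_of_model(m)
        )
        # both termini share the single origin, so the three blocks close
        # into a cycle through it
        assert len(pre.vertices) == 3
        assert len(pre.edges) == 3
        assert verify_cactus(pre)

    def test_empty_enredo_gives_origin_only(self):
        from gagraphs.enredo import EnredoStructure

        pre, _, _ = build_precursor(
            EnredoStructure(frozenset(), frozenset(), {})
        )
        assert pre.vertices == frozenset({pre.origin})

    def test_merge_3ec_three_parallel_edges(self):
        c = CactusStructure(
            frozenset({"origin", "v"}),
            "origin",
            {"e1": ("origin", "v"), "e2": ("origin", "v"), "e3": ("origin", "v")},
        )
        merged, vmap = merge_3ec(c)
        assert len(merged.vertices) == 1
        assert all(u == w for u, w in merged.edges.values())

    def test_merge_3ec_keeps_simple_cycle(self):
        c = CactusStructure(
            frozenset({"origin", "a", "b"}),
            "origin",
            {"e1": ("origin", "a"), "e2": ("a", "b"), "e3": ("b", "origin")},
        )
        merged, _ = merge_3ec(c)
        assert merged.vertices == c.vertices

    @pytest.mark.parametrize("seed", range(12))
    def test_merge_3ec_against_cut_enumeration(self, seed):
        """After merging, no two vertices admit a min edge cut >= 3,
        checked by enumerating all cuts of up to two edges."""
        import random

        rng = random.Random(seed)
        n = rng.randint(3, 5)
        vertices = ["origin"] + [f"v{i}" for i in range(n)]
        edges = {}
        for k in range(rng.randint(n, 2 * n)):
            u, w = rng.sample(vertices, 2)
            edges[f"e{k}"] = (u, w)
        c = CactusStructure(frozenset(vertices), "origin", edges)
        merged, _ = merge_3ec(c)

        def three_connected(c, u, w):
            g = nx.MultiGraph()
            g.add_nodes_from(c.vertices)
            for eid, (a, b) in c.edges.items():
                if a != b:
                    g.add_edge(a, b, key=eid)
            if not nx.has_path(g, u, w):
                return False
            keys = [(a, b, k) for a, b, k in g.edges(keys=True)]
            for removal in itertools.chain(
                [()],
                itertools.combinations(keys, 1),
                itertools.combinations(keys, 2),
            ):
                h = g.copy()
                for a, b, k in removal:
                    h.remove_edge(a, b, key=k)
                if not nx.has_path(h, u, w):
                    return False
            return True

        for u, w in itertools.combinations(sorted(merged.vertices), 2):
            assert not three_connected(merged, u, w)

    def test_bridge_path_collapses_to_self_loops(self):
        c = CactusStructure(
            frozenset({"origin", "a", "b", "c"}),
            "origin",
            {"e1": ("origin", "a"), "e2": ("a", "b"), "e3": ("b", "c")},
        )
        out, _ = collapse_bridge_trees(c)
        assert len(out.vertices) == 1
        assert all(u == w for u, w in out.edges.values())

    def test_pure_cycle_unchanged_by_bridge_collapse(self):
        c = CactusStructure(
            frozenset({"origin", "a", "b"}),
            "origin",
            {"e1": ("origin", "a"), "e2": ("a", "b"), "e3": ("b", "origin")},
        )
        out, _ = collapse_bridge_trees(c)
        assert out.vertices == c.vertices

    def test_verify_cactus_examples(self):
        tree = CactusStructure(
            frozenset({"origin", "a", "b"}),
            "origin",
            {"e1": ("origin", "a"), "e2": ("a", "b")},
        )
        assert verify_cactus(tree)
        k4_edges = {}
        nodes = ["origin", "a", "b", "c"]
        for i, (u, w) in enumerate(itertools.combinations(nodes, 2)):
            k4_edges[f"e{i}"] = (u, w)
        k4 = CactusStructure(frozenset(nodes), "origin", k4_edges)
        assert not verify_cactus(k4)

    def test_two_cycles_sharing_a_vertex_are_a_cactus(self):
        c = CactusStructure(
            frozenset({"origin", "a", "b"}),
            "origin",
            {
                "e1": ("origin", "a"),
                "e2": ("a", "origin"),
                "e3": ("origin", "b"),
                "e4": ("b", "origin"),
            },
        )
        assert verify_cactus(c)
        assert len(chains(c)) == 2

    @pytest.mark.parametrize("seed", range(25))
    def test_build_cactus_guarantees(self, seed):
        bs = random_blockset(seed)
        en, _ = build_enredo(bs)
        ca = build_cactus(en)
        assert verify_cactus(ca.structure)
        assert verify_eulerian(ca)

    def test_eulerian_counterexample(self):
        # one edge of multiplicity one between two vertices: odd degrees
        bs = layout_blockset({"g1": [("A", "+")]})
        en, _ = build_enredo(bs)
        ca = build_cactus(en)
        assert verify_eulerian(ca)  # self-loop at origin: even
        from gagraphs.cactus import CactusModel

        odd = CactusStructure(
            frozenset({"origin", "v"}), "origin", {"e": ("origin", "v")}
        )
        bad = CactusModel(
            odd, {"e": en.labels[next(iter(en.labels))]}, ca.adj_labels,
            {}, en,
        )
        assert not verify_eulerian(bad)

    @pytest.mark.parametrize("seed", range(15))
    def test_chains_match_cycle_enumeration(self, seed):
        bs = random_blockset(seed)
        en, _ = build_enredo(bs)
        ca = build_cactus(en)
        assert chains(ca.structure) == brute_force_simple_cycles(ca.structure)

    def test_conserved_chain_in_eleven_block_fixture(self):
        en, _ = build_enredo(fixture("fig4"))
        ca = build_cactus(en)
        named = {
            frozenset(str(ca.labels[e].id) for e in chain)
            for chain in chains(ca.structure)
        }
        assert frozenset("AEIK") in named

    def test_chain_blocks_not_contiguous_in_genomes(self):
        # the conserved chain A,E,I,K is spread across each genome: its
        # subgraph in the other representations is disconnected
        bs = fixture("fig4")
        for g in bs.genomes:
            order = [str(b.id) for _, b in bs.segments_in_order(g)]
            positions = [i for i, x in enumerate(order) if x in "AEIK"]
            assert any(
                b - a > 1 for a, b in zip(positions, positions[1:])
            )

    def test_groups_refine_cactus_vertices(self):
        bs = fixture("fig4")
        en, _ = build_enredo(bs)
        ca = build_cactus(en)
        gs = groups(en.structure)
        # each group's adjacency edges map into a single cactus vertex
        for grp in gs:
            images = {
                ca.vertex_map[en.structure.adjacency_edges[e][0]]
                for e in grp
            }
            assert len(images) == 1

    def test_forward_chain_groups(self):
        bs = layout_blockset({"g1": [("A", "+"), ("B", "+"), ("C", "+")]})
        en, _ = build_enredo(bs)
        assert len(groups(en.structure)) == 2  # one per interior boundary

    def test_fixture_vertex_adjacency_counts(self):
        # consistency check of the reconstruction: the three interior
        # cactus vertices hold twelve, eleven and seven adjacencies
        bs = fixture("fig4")
        en, _ = build_enredo(bs)
        ca = build_cactus(en)
        from collections import Counter

        counts = Counter(
            ca.vertex_map[u]
            for u, _ in en.structure.adjacency_edges.values()
        )
        assert sorted(counts.values(), reverse=True) == [12, 11, 7]

    def test_rebuild_from_retained_enredo_is_isomorphic(self):
        bs = random_blockset(3)
        en, _ = build_enredo(bs)
        ca1 = build_cactus(en)
        ca2 = build_cactus(ca1.enredo)
        assert isomorphic(ca1.structure, ca2.structure)
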