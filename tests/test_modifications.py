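"""The four elementary modifications and segmentation finalisation."""

import pytest

from gagraphs.core import Block, BlockSet, HEAD, Position, Segment, TAIL, validate_tiling
from gagraphs.modifications import (
    SegmentationState,
    cut_adjacency,
    finalize_segmentation,
    merge_consecutive_blocks,
    merge_parallel_blocks,
    split_block,
)
from gagraphs.substructures import (
    detect_visiting_blocks,
    find_cycles,
    maximal_colinear_paths,
)
from gagraphs.synthetic import fixture, generate

from conftest import layout_blockset, random_blockset


class TestSplit:
    def test_splitting_visiting_block_empties_redetection(self):
        bs = fixture("fig8_top")
        (v,) = detect_visiting_blocks(bs)
        p = v.path.blocks[0]
        subset = [s for s in p.canonical.segments if s.genome in ("g1", "g2")]
        out = split_block(bs, p, subset)
        assert validate_tiling(out) == []
        assert detect_visiting_blocks(out) == []

    def test_split_size_two_block(self):
        bs = layout_blockset(
            {"g1": [("A", "+")], "g2": [("A", "+")]}
        )
        a = bs.block_by_id("A")
        out = split_block(bs, a, [a.canonical.segments[0]])
        assert sorted(b.size for b in out.blocks) == [1, 1]

    def test_empty_and_full_subsets_rejected(self):
        bs = layout_blockset({"g1": [("A", "+")], "g2": [("A", "+")]})
        a = bs.block_by_id("A")
        with pytest.raises(ValueError):
            split_block(bs, a, [])
        with pytest.raises(ValueError):
            split_block(bs, a, list(a.canonical.segments))

    @pytest.mark.parametrize("seed", range(15))
    def test_split_then_merge_parallel_is_identity(self, seed):
        bs = random_blockset(seed, p_inversion=0.4)
        b = next(x for x in bs.blocks if x.size >= 2)
        subset = list(b.canonical.segments)[: b.size // 2 or 1]
        sp = split_block(bs, b, subset)
        p1 = next(x for x in sp.blocks if str(x.id) == f"{b.id}/1")
        p2 = next(x for x in sp.blocks if str(x.id) == f"{b.id}/2")
        merged_same = merge_parallel_blocks(sp, p1, p2, "same")
        merged_opp = merge_parallel_blocks(sp, p1, p2, "opposite")
        assert merged_same == bs or merged_opp == bs

    def test_tiling_preserved(self):
        for seed in range(10):
            bs = random_blockset(seed)
            b = next(x for x in bs.blocks if x.size >= 2)
            out = split_block(bs, b, [b.canonical.segments[0]])
            assert validate_tiling(out) == []


class TestMergeParallel:
    def test_two_way_cycle_eliminated(self):
        bs = layout_blockset(
            {
                "g1": [("A", "+"), ("B", "+"), ("D", "+")],
                "g2": [("A", "+"), ("C", "+"), ("D", "+")],
            }
        )
        assert find_cycles(bs)
        out = merge_parallel_blocks(
            bs, bs.block_by_id("B"), bs.block_by_id("C"), "same"
        )
        assert validate_tiling(out) == []
        assert find_cycles(out) == []
        assert len(maximal_colinear_paths(out)) == 1

    def test_sizes_add(self):
        for seed in range(10):
            bs = random_blockset(seed)
            b1, b2 = bs.blocks[0], bs.blocks[1]
            out = merge_parallel_blocks(bs, b1, b2)
            merged = next(
                b for b in out.blocks if b.size == b1.size + b2.size
            )
            assert merged.size == b1.size + b2.size

    def test_identical_blocks_rejected(self):
        bs = layout_blockset({"g1": [("A", "+"), ("B", "+")]})
        a = bs.block_by_id("A")
        with pytest.raises(ValueError):
            merge_parallel_blocks(bs, a, a)


class TestMergeConsecutive:
    def test_forward_chain_concatenation(self):
        bs = layout_blockset(
            {f"g{i}": [("A", "+"), ("B", "+")] for i in range(3)},
            lengths={"A": 2, "B": 3},
        )
        out = merge_consecutive_blocks(
            bs, bs.block_by_id("A"), bs.block_by_id("B")
        )
        (merged,) = out.blocks
        assert merged.size == 3
        assert all(s.length == 5 for s in merged.segments)
        assert validate_tiling(out) == []

    def test_inverted_pair_concatenates(self):
        # B inverted in every genome relative to A: the (head, head)
        # adjacency is still breakpoint-free and merges after flipping
        bs = layout_blockset(
            {f"g{i}": [("A", "+"), ("B", "-")] for i in range(2)},
            lengths={"A": 2, "B": 3},
        )
        out = merge_consecutive_blocks(
            bs, bs.block_by_id("A"), bs.block_by_id("B")
        )
        (merged,) = out.blocks
        assert merged.size == 2 and all(s.length == 5 for s in merged.segments)
        assert validate_tiling(out) == []

    def test_breakpoint_refused(self):
        bs = layout_blockset(
            {
                "g1": [("A", "+"), ("B", "+")],
                "g2": [("A", "+"), ("B", "+")],
                "g3": [("A", "+"), ("C", "+"), ("B", "+")],
            }
        )
        with pytest.raises(ValueError):
            merge_consecutive_blocks(
                bs, bs.block_by_id("A"), bs.block_by_id("B")
            )

    def test_merging_along_paths_reduces_to_path_count(self):
        bs = random_blockset(9, p_inversion=0.4, p_translocation=0.4,
                             p_duplication=0.0)
        n_paths = len(maximal_colinear_paths(bs))
        changed = True
        while changed:
            changed = False
            for p in maximal_colinear_paths(bs):
                if len(p.blocks) > 1:
                    bs = merge_consecutive_blocks(bs, p.blocks[0], p.blocks[1])
                    changed = True
                    break
        assert len(bs.blocks) == n_paths
        # afterwards every remaining adjacency is a breakpoint
        assert all(len(p.blocks) == 1 for p in maximal_colinear_paths(bs))


class TestCut:
    def test_cut_records_one_position_per_segment(self):
        bs = layout_blockset(
            {f"g{i}": [("A", "+"), ("B", "+")] for i in range(3)}
        )
        state = cut_adjacency(SegmentationState(), bs.block_by_id("A"), TAIL)
        assert len(state.cuts) == 3

    def test_cuts_only_grow(self):
        bs = layout_blockset({"g1": [("A", "+"), ("B", "+")]})
        s0 = SegmentationState()
        s1 = cut_adjacency(s0, bs.block_by_id("A"), TAIL)
        s2 = cut_adjacency(s1, bs.block_by_id("B"), HEAD)
        assert s0.cuts <= s1.cuts <= s2.cuts

    def test_cutting_everything_yields_tiling_itself(self):
        bs = random_blockset(2, p_duplication=0.0)
        state = SegmentationState()
        for b in bs.blocks:
            state = cut_adjacency(state, b, HEAD)
            state = cut_adjacency(state, b, TAIL)
        segs = finalize_segmentation(bs, state)
        expected = {
            (s.genome, s.start, s.end)
            for b in bs.blocks
            for s in b.segments
        }
        assert {(s.genome, s.start, s.end) for s in segs} == expected

    def test_block_set_unchanged_by_cut(self):
        bs = layout_blockset({"g1": [("A", "+"), ("B", "+")]})
        before = bs
        cut_adjacency(SegmentationState(), bs.block_by_id("A"), TAIL)
        assert bs == before


class TestSegmentation:
    def test_fully_colinear_single_segment_per_genome(self):
        bs = generate(5).block_set
        segs = finalize_segmentation(bs)
        assert len(segs) == len(bs.genomes)
        for s in segs:
            assert (s.start, s.end) == (0, bs.genome_lengths[s.genome])

    def test_competing_interpretations_segment_counts(self):
        from collections import Counter

        si = Counter(
            s.genome
            for s in finalize_segmentation(fixture("fig1_inversion"))
        )
        st = Counter(
            s.genome
            for s in finalize_segmentation(fixture("fig1_translocation"))
        )
        assert set(si.values()) == {3}
        assert set(st.values()) == {4}

    @pytest.mark.parametrize("seed", range(15))
    def test_boundaries_are_breakpoints_plus_cuts(self, seed):
        from gagraphs.core import adjacencies_between, is_breakpoint

        bs = random_blockset(seed)
        b = bs.blocks[0]
        state = cut_adjacency(SegmentationState(), b, TAIL)
        segs = finalize_segmentation(bs, state)
        for g in bs.genomes:
            got = sorted(
                {s.start for s in segs if s.genome == g}
                | {s.end for s in segs if s.genome == g}
            )
            expected = {0, bs.genome_lengths[g]}
            expected |= {
                p.offset for p in state.cuts if p.genome == g
            }
            for bd in bs.boundaries():
                if bd.position.genome != g:
                    continue
                cls = next(
                    ac
                    for ac in adjacencies_between(
                        bd.left_block, bd.right_block, bs
                    )
                    if bd.position in ac.positions
                )
                if is_breakpoint(cls, bd.left_block, bd.right_block):
                    expected.add(bd.position.offset)
            assert got == sorted(expected)

    def test_every_offset_covered_once(self):
        bs = random_blockset(11)
        segs = finalize_segmentation(bs)
        for g in bs.genomes:
            spans = sorted(
                (s.start, s.end) for s in segs if s.genome == g
            )
            cursor = 0
            for a, b in spans:
                assert a == cursor
                cursor = b
            assert cursor == bs.genome_lengths[g]
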