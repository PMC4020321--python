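import random

import pytest

from gagraphs.core import Block, BlockSet, Segment
from gagraphs.synthetic import fixture, generate


@pytest.fixture
def fig6():
    return fixture("fig6")


@pytest.fixture
def fig5_pair():
    return fixture("fig5_forward"), fixture("fig5_inverted")


def random_blockset(seed: int, **kwargs) -> BlockSet:
    """A random tiling with rearrangements; defaults keep instances small
    enough for brute-force oracles."""
    params = dict(
        n_genomes=3,
        n_blocks=5,
        p_inversion=0.3,
        p_duplication=0.25,
        p_translocation=0.25,
    )
    params.update(kwargs)
    return generate(seed, **params).block_set


def layout_blockset(layout, lengths=None) -> BlockSet:
    """Build a block set from per-genome (block, orientation) lists."""
    from gagraphs.synthetic import _from_layout

    return _from_layout(layout, lengths)


def random_segments(rng: random.Random, genome_len: int = 6):
    """All segments of a small genome, both orientations."""
    out = []
    for a in range(genome_len):
        for b in range(a + 1, genome_len + 1):
            out.append(Segment("g", a, b))
            out.append(Segment("g", b, a))
    return out
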