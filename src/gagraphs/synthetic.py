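"""Seeded generator of genomes with planted rearrangements, plus the small
worked-example fixtures used throughout the documentation and tests.

The generator emulates the output of the local-alignment stage of a genome
aligner: a ground-truth block set tiling the genomes, together with the
event log of every planted inversion, duplication (tandem, inverted-tandem
= palindrome, or dispersed) and translocation.  Genome 0 is kept as an
unmodified reference so that every planted event leaves a detectable trace.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Mapping, NamedTuple

from .core import Block, BlockSet, Segment

__all__ = ["Event", "SimulationResult", "generate", "fixture", "FIXTURES"]

_ALPHABET = "ACGT"


class Event(NamedTuple):
    genome: str
    kind: str  # inversion | duplication | translocation
    block: str
    detail: str  # e.g. duplication placement: tandem | palindrome | dispersed


@dataclass(frozen=True)
class SimulationResult:
    sequences: Mapping[str, str]
    block_set: BlockSet
    events: tuple[Event, ...]


def generate(
    seed: int,
    n_genomes: int = 3,
    n_blocks: int = 8,
    block_length_range: tuple[int, int] = (2, 12),
    p_inversion: float = 0.0,
    p_duplication: float = 0.0,
    p_translocation: float = 0.0,
) -> SimulationResult:
    """Plant rearrangements on an initially colinear chain of blocks.

    Per non-reference genome and per block, an inversion, a duplication and
    a translocation are each planted with the given Bernoulli probability,
    in that order.  With all probabilities zero the result is a fully
    colinear alignment: every block has one segment per genome and the
    whole alignment is a single maximal colinear path.

    Deterministic per seed; the returned block set always passes the tiling
    validation, and the event log names every planted event.
    """
    for p in (p_inversion, p_duplication, p_translocation):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if n_genomes < 1 or n_blocks < 1:
        raise ValueError("need at least one genome and one block")
    lo, hi = block_length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid block length range")
    rng = random.Random(seed)
    names = [f"b{i}" for i in range(n_blocks)]
    lengths = {b: rng.randint(lo, hi) for b in names}
    content = {
        b: "".join(rng.choice(_ALPHABET) for _ in range(lengths[b]))
        for b in names
    }
    genomes = [f"g{i}" for i in range(n_genomes)]
    # occurrence lists: (block, orientation, token); tokens identify
    # occurrences so that planted tandem/palindrome pairs stay intact
    token = iter(range(10**9))
    occ: dict[str, list[tuple[str, str, int]]] = {
        g: [(b, "+", next(token)) for b in names] for g in genomes
    }
    events: list[Event] = []
    for g in genomes[1:]:
        bonds: set[tuple[int, int]] = set()  # adjacent token pairs to keep

        def insertable(j: int) -> bool:
            if j == 0 or j == len(occ[g]):
                return True
            return (occ[g][j - 1][2], occ[g][j][2]) not in bonds

        for b in names:
            if rng.random() < p_inversion:
                idx = [i for i, (x, _, _) in enumerate(occ[g]) if x == b]
                i = rng.choice(idx)
                blk, o, tk = occ[g][i]
                occ[g][i] = (blk, "-" if o == "+" else "+", tk)
                events.append(Event(g, "inversion", b, f"occurrence {i}"))
        duplicated: set[str] = set()
        for b in names:
            if rng.random() < p_duplication:
                idx = [i for i, (x, _, _) in enumerate(occ[g]) if x == b]
                i = rng.choice(idx)
                blk, o, tk = occ[g][i]
                placement = rng.choice(["tandem", "palindrome", "dispersed"])
                if placement == "tandem":
                    new = (blk, o, next(token))
                    occ[g].insert(i + 1, new)
                    bonds.add((tk, new[2]))
                elif placement == "palindrome":
                    new = (blk, "-" if o == "+" else "+", next(token))
                    occ[g].insert(i + 1, new)
                    bonds.add((tk, new[2]))
                else:
                    slots = [
                        j for j in range(len(occ[g]) + 1) if insertable(j)
                    ]
                    occ[g].insert(
                        rng.choice(slots), (blk, rng.choice("+-"), next(token))
                    )
                duplicated.add(b)
                events.append(Event(g, "duplication", b, placement))
        for b in names:
            if b in duplicated:
                continue  # keep planted duplication patterns intact
            if rng.random() < p_translocation:
                idx = [i for i, (x, _, _) in enumerate(occ[g]) if x == b]
                i = rng.choice(idx)
                item = occ[g].pop(i)
                slots = [j for j in range(len(occ[g]) + 1) if insertable(j)]
                j = rng.choice(slots)
                occ[g].insert(j, item)
                events.append(Event(g, "translocation", b, f"to slot {j}"))
    # materialise coordinates and sequences
    sequences: dict[str, str] = {}
    segments: dict[str, list[Segment]] = {b: [] for b in names}
    for g in genomes:
        parts: list[str] = []
        cursor = 0
        for b, o, _tk in occ[g]:
            L = lengths[b]
            if o == "+":
                parts.append(content[b])
                segments[b].append(Segment(g, cursor, cursor + L))
            else:
                parts.append(_revcomp(content[b]))
                segments[b].append(Segment(g, cursor + L, cursor))
            cursor += L
        sequences[g] = "".join(parts)
    blocks = [Block(b, segs) for b, segs in segments.items()]
    bs = BlockSet({g: len(sequences[g]) for g in genomes}, blocks)
    return SimulationResult(sequences, bs, tuple(events))


def _revcomp(s: str) -> str:
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


# ---------------------------------------------------------------------------
# worked-example fixtures


def _from_layout(
    layout: Mapping[str, list[tuple[str, str]]],
    lengths: Mapping[str, int] | None = None,
) -> BlockSet:
    """Build a block set from per-genome occurrence lists of
    (block, orientation); every occurrence of one block shares its
    length (default 1)."""
    segments: dict[str, list[Segment]] = {}
    genome_lengths: dict[str, int] = {}
    for g, occ in layout.items():
        cursor = 0
        for b, o in occ:
            L = 1 if lengths is None else lengths.get(b, 1)
            seg = (
                Segment(g, cursor, cursor + L)
                if o == "+"
                else Segment(g, cursor + L, cursor)
            )
            segments.setdefault(b, []).append(seg)
            cursor += L
        genome_lengths[g] = cursor
    return BlockSet(
        genome_lengths, [Block(b, segs) for b, segs in segments.items()]
    )


def _spell(word: str) -> list[tuple[str, str]]:
    return [(ch, "+") for ch in word]


def _fixtures() -> dict[str, BlockSet]:
    out: dict[str, BlockSet] = {}

    # Two 6 bp sequences CATCGA / CCGATA with two competing interpretations:
    # an inversion of the central ATCG (three blocks per genome) or a
    # translocation of AT against CG (four blocks per genome).
    out["fig1_inversion"] = BlockSet(
        {"g1": 6, "g2": 6},
        [
            Block("C", [Segment("g1", 0, 1), Segment("g2", 0, 1)]),
            Block("ATCG", [Segment("g1", 1, 5), Segment("g2", 5, 1)]),
            Block("A", [Segment("g1", 5, 6), Segment("g2", 5, 6)]),
        ],
    )
    out["fig1_translocation"] = BlockSet(
        {"g1": 6, "g2": 6},
        [
            Block("C", [Segment("g1", 0, 1), Segment("g2", 0, 1)]),
            Block("AT", [Segment("g1", 1, 3), Segment("g2", 3, 5)]),
            Block("CG", [Segment("g1", 3, 5), Segment("g2", 1, 3)]),
            Block("A", [Segment("g1", 5, 6), Segment("g2", 5, 6)]),
        ],
    )

    # Two genomes ABC / ABC and ABC / A(B-)C: one of them inverts block B.
    out["fig5_forward"] = _from_layout(
        {"g1": _spell("ABC"), "g2": _spell("ABC")}
    )
    out["fig5_inverted"] = _from_layout(
        {"g1": _spell("ABC"), "g2": [("A", "+"), ("B", "-"), ("C", "+")]}
    )

    # One genome ABDABCEBC: duplications of A, B and C make the block order
    # ambiguous (the same structure threads as ABCEBDABC).
    out["fig6"] = _from_layout({"g1": _spell("ABDABCEBC")})

    # Both blocks occur three times, twice forward and once reverse
    # complemented; with only per-vertex orientation bit multisets, the
    # combination of the orientations remains ambiguous.
    out["fig7"] = _from_layout(
        {
            "g1": [
                ("A", "+"),
                ("B", "+"),
                ("A", "+"),
                ("B", "+"),
                ("A", "-"),
                ("B", "-"),
            ]
        }
    )

    # Visiting block: the path {P} is traversed consistently (every run
    # entering from U exits into X) at the top; inconsistently at the
    # bottom.  The two A-Bruijn structures are identical.
    out["fig8_top"] = _from_layout(
        {
            "g1": [("U", "+"), ("P", "+"), ("X", "+")],
            "g2": [("U", "+"), ("P", "+"), ("X", "+")],
            "g3": [("V", "+"), ("P", "+"), ("Y", "+")],
        }
    )
    out["fig8_bottom"] = _from_layout(
        {
            "g1": [("U", "+"), ("P", "+"), ("X", "+")],
            "g2": [("U", "+"), ("P", "+"), ("Y", "+")],
            "g3": [("V", "+"), ("P", "+"), ("X", "+")],
        }
    )

    # An inversion of block A creates a cycle visible in the Enredo
    # structure but not in the A-Bruijn structure.
    out["fig9b"] = _from_layout(
        {"g1": [("A", "+"), ("B", "+")], "g2": [("A", "-"), ("B", "+")]}
    )

    # Deletion bulge: block B present in the red genome only.  The cycle is
    # formed by the path {B} and the flanking blocks A and C; whether it is
    # a whirl or a bulge depends on the chosen genome orientations.
    out["fig10"] = _from_layout(
        {
            "red": _spell("ABC"),
            "blue": [("A", "+"), ("C", "+")],
        },
        lengths={"A": 2, "B": 1, "C": 2},
    )

    # Palindrome (inverted tandem duplication) vs direct tandem repeat;
    # indistinguishable in alignment and A-Bruijn structures.
    out["fig11_palindrome"] = _from_layout(
        {"g1": [("X", "+"), ("A", "+"), ("A", "-"), ("Y", "+")]},
        lengths={"X": 2, "A": 3, "Y": 2},
    )
    out["fig11_tandem"] = _from_layout(
        {"g1": [("X", "+"), ("A", "+"), ("A", "+"), ("Y", "+")]},
        lengths={"X": 2, "A": 3, "Y": 2},
    )

    # A reconstruction of the three-genome, eleven-block overview example:
    # A, E, I, K conserved in all three genomes; B, C, D and G, H reordered
    # and partly inverted; F missing from the red genome; J duplicated.
    out["fig4"] = _from_layout(
        {
            "red": [
                ("A", "+"), ("B", "+"), ("C", "+"), ("D", "+"), ("E", "+"),
                ("G", "+"), ("H", "+"), ("I", "+"), ("J", "+"), ("J", "+"),
                ("K", "+"),
            ],
            "blue": [
                ("A", "+"), ("D", "+"), ("B", "-"), ("C", "+"), ("E", "+"),
                ("F", "+"), ("H", "-"), ("G", "+"), ("I", "+"), ("J", "+"),
                ("K", "+"),
            ],
            "green": [
                ("A", "+"), ("C", "+"), ("D", "-"), ("B", "+"), ("E", "+"),
                ("F", "+"), ("G", "-"), ("H", "+"), ("I", "+"), ("J", "+"),
                ("K", "+"),
            ],
        },
        lengths={ch: 2 for ch in "ABCDEFGHIJK"},
    )
    return out


FIXTURES = sorted(_fixtures())


def fixture(name: str) -> BlockSet:
    """A named worked-example block set; see :data:`FIXTURES`."""
    table = _fixtures()
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}"
        ) from None
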