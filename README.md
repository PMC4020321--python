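# gagraphs

Graph data structures for whole-genome alignment.

Non-colinear genome alignment — multiple alignment in the presence of
inversions, duplications and translocations — is usually carried out on a
graph built from a set of local alignments. The field has produced several
such graphs: **alignment graphs** (a vertex per aligned segment),
**A-Bruijn graphs** (a vertex per block), **Enredo graphs** (head and tail
vertices per block) and **cactus graphs** (vertices are sets of
adjacencies, edges are blocks). They all encode the same underlying object
— a set of *blocks*, each a colinear alignment of genomic segments, tiling
the genomes — but their *structures* retain different subsets of the
alignment information.

`gagraphs` is a library and command-line tool for working with this family
of representations. It is aimed at developers of genome aligners and at
anyone studying rearrangements who wants to move between the
representations, detect the substructures that signal misalignment, and
apply the elementary modifications that eliminate them.

## The model

A genome `g` is a sequence over {A,C,G,T}; a *position* is `p = (g, i)`
with `0 ≤ i < |g|`. A *segment* is an ordered position pair `s = (p, q)`
on one genome: `p < q` is the forward strand, `p > q` the reverse
complement; the segment covers the half-open interval
`[min(p,q), max(p,q))`. A *block* `b` is a colinear alignment of segments
(possibly several from one genome), with a *head* (the `p` endpoints) and a
*tail* (the `q` endpoints). A block set `B_G` must tile the genomes:
blocks are pairwise non-overlapping and unaligned stretches are covered by
size-1 blocks. Two blocks are *adjacent* where their segments abut — up to
four adjacency classes (head/tail × head/tail) per pair — and an adjacency
held by only a subset of a block's segments is a *breakpoint*.

On top of this model the package provides:

- **the four graphs** as separate *structure* (vertices + edges) and
  *model* (structure + labeling) types, each with exact block-set recovery;
- **the six structure transformations** between them, together with the
  three sparse labelings that resolve the ambiguous directions —
  `ℓ_dup` (a total order on adjacency edges), `ℓ_inv` (orientation bits)
  and `ℓ_adj` (per-segment orientation + global order) — and a brute-force
  enumerator of all target structures consistent with a source structure;
- **substructure detectors**: maximal colinear paths, visiting blocks,
  genome-alignment cycles (classified as whirl / bulge / composite and by
  the number of maximal colinear paths), palindromes, cactus chains and
  groups, plus the structure-level visibility matrix;
- **the four elementary modifications**: splitting a block, merging
  parallel blocks, merging consecutive blocks, and cutting adjacencies,
  plus the final genome segmentation;
- **a seeded generator** of genomes with planted inversions, duplications
  (tandem, palindromic, dispersed) and translocations, with a ground-truth
  block set and event log.

## A worked example

The single genome `ABDABCEBC` (nine segments; equal letters aligned into
one block each) is the classic illustration of duplication ambiguity:

```python
>>> import gagraphs as G
>>> bs = G.fixture("fig6")
>>> model, dup, inv = G.build_abruijn(bs)
>>> len(model.structure.vertices), len(model.structure.edges)
(5, 8)
>>> [v for _, v in G.thread_genome_ab(model, dup, "g1")]
['A', 'B', 'D', 'A', 'B', 'C', 'E', 'B', 'C']
>>> sorted(len(t[0]) for t in G.enumerate_threadings(model.structure))
[9, 9]
```

The A-Bruijn graph has five vertices (blocks A, B, C, D, E) and eight
adjacency edges, carrying duplication labels 1..8. Without those labels
the structure threads in exactly **two** ways — it represents both
`ABDABCEBC` and `ABCEBDABC`, so the block order is ambiguous. Inversions
behave the other way around: the block sets {`ABC`, `ABC`} and
{`ABC`, `AB̄C`} have isomorphic alignment and A-Bruijn structures but two
distinct Enredo structures:

```python
>>> e1, _ = G.build_enredo(G.fixture("fig5_forward"))
>>> e2, _ = G.build_enredo(G.fixture("fig5_inverted"))
>>> G.isomorphic(e1.structure, e2.structure)
False
```

## Command line

```sh
gagraphs simulate --seed 3 --out-prefix sim        # FASTA + block TSV + events
gagraphs validate sim.blocks.tsv --fasta sim.fa    # tiling check
gagraphs build sim.blocks.tsv --graph enredo --dot graph.dot
gagraphs detect sim.blocks.tsv --kind cycles
gagraphs convert sim.blocks.tsv --from abruijn --to enredo --with-labels
gagraphs modify sim.blocks.tsv --op split --block b3 --genomes g1 --out out.tsv
gagraphs segment out.tsv --out out.bed
gagraphs pipeline sim.blocks.tsv --out-prefix run  # build→detect→eliminate→segment
```

Blocks are exchanged as TSV (`block_id  genome  start  end  strand`,
0-based half-open); segmentations as BED; graphs as DOT.

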