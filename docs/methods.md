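# Methods

This note records the model assumptions, conventions, numerical and design
choices behind `gagraphs`, and what the synthetic tests do and do not show.

## Coordinate and orientation conventions

Coordinates are 0-based, half-open. A segment is an ordered endpoint pair
`(p, q)`; `p < q` is forward, `p > q` reverse complement, and the covered
interval is `[min, max)` — the larger endpoint is the position directly
following the last covered character. Genomes carry a strict total order
(lexicographic on identifier), which totally orders positions and hence
adjacency edges.

Every block has two equivalent representations (as given / everything
reverse complemented). The **canonical representation** is the one in
which the segment with the smallest minimum position is forward; it fixes
head/tail naming, serialization and all derived vertex ids, making every
build deterministic.

For block ends we use the edge-endpoint convention of the two-vertex
(Enredo-style) graph throughout the package, including the core adjacency
classes: a forward segment *enters* its block at the tail vertex and
*exits* at the head vertex; a reverse-complemented segment enters at the
head and exits at the tail. Consequently two forward blocks `A B` meet in
a head(A)–tail(B) adjacency. Classifying a boundary from the opposite
strand swaps both roles at once, so adjacency classes are well defined per
(ordered) block pair; flipping one block's representation swaps the end
names of its classes without changing any position set or breakpoint
verdict.

## Graph constructions

- *Alignment graph*: vertex per segment (`genome:rank` ids), directed
  adjacency edges in genomic left-to-right direction, block edges stored
  as explicit cliques. Cliques, not just components, so that splitting a
  block maps to deleting block edges.
- *A-Bruijn graph*: vertex per block, one individually identified directed
  edge per adjacent segment pair (a true multigraph, not multiplicity
  counters). `ℓ_dup` ranks are dense, `1..|E|`, in adjacency position
  order across the concatenated genomes. The `DupLabels` object also
  records each edge's genome: threading follows each genome separately,
  and that per-genome grouping (the "edge colors") is part of the
  duplication information; rank numbers alone cannot say where one genome
  ends and the next begins.
- *Enredo graph*: tail/head vertex pair and one block edge per block;
  adjacency edge endpoints chosen by the entry/exit rule above. Size-1
  blocks are kept as block edges by default; `collapse_size1_blocks` is an
  explicit opt-in that turns an interior size-1 block into a
  segment-labeled adjacency edge. Terminal size-1 blocks are never
  collapsed (the replacement rule needs an adjacency edge on both sides),
  and a collapsed edge is never collapsed again, so a run of k adjacent
  size-1 blocks collapses only one block per pass — the segment label
  holds exactly one segment. Parallel adjacency edges with identical
  endpoints are never merged.
- *Cactus graph*: three construction steps — contract adjacency-edge
  connected components (one shared origin vertex absorbs every component
  containing a genome terminus), merge 3-edge-connected vertex sets,
  collapse bridge-only trees. 3-edge-connectivity is decided by repeated
  max-flow between vertex pairs; at the desk scales this package targets
  (tens of blocks) the quadratic cost is irrelevant, and an asymptotically
  optimal algorithm would merge the same classes. The Eulerian check
  counts each edge with multiplicity equal to its block's size — the only
  reading under which the circuit traverses every genome segment exactly
  once. The cactus model retains the Enredo model it was built from.

## Sparse labelings and threading

`ℓ_inv` on A-Bruijn edges is the pair (orientation of source segment,
orientation of target segment). `ℓ_adj` on cactus edges lists, per segment
of the edge's block, an orientation bit and a global segment number. The
numbers impose the global left-to-right order (genomes concatenated in
their total order); numbering is consecutive within one genome and skips
one value at each genome boundary. The gap is deliberate: the
cactus-to-Enredo threading walks the labels in increasing order and must
know when to restart at the origin, and a cactus vertex merged with the
origin can also occur mid-genome, so "walk is at the origin" is not a
usable end-of-genome signal.

## Isomorphism and the ambiguity enumerator

Ambiguity counts are measured up to *type-preserving isomorphism*: edge
types (block vs adjacency), adjacency direction and the origin vertex are
invariants; block-edge pairing is preserved because block edges are part
of the matched edge set. Matching uses VF2 on a networkx encoding, with a
degree-profile fingerprint for bucketing.

`enumerate_consistent` mechanizes the ambiguity arguments by exhaustive
search: threadings are all partitions of the A-Bruijn edge multiset into
per-genome trails; orientation assignments attach a bit to every block
occurrence, optionally constrained by per-vertex bit multisets with `*`
wildcards (this expresses "one orientation bit per segment on the
vertices", whose insufficiency the two-blocks-three-occurrences example
demonstrates). For the two-genome inversion example, the enumeration
pinned to everything except one block orientation returns exactly the two
published alternatives; unconstrained enumeration returns more (every
consistent orientation pattern), which still witnesses the ambiguity — the
two-structure figure exhibits a minimal pair rather than the full count.
Cactus-to-Enredo enumeration walks bounded origin-to-origin tours. All
enumerations are exponential and guarded by size caps (default 12 blocks /
30 edges); they exist to verify claims on worked examples, not to scale.

## Substructures

Maximal colinear paths are assembled from *full links*: adjacency classes
covering every segment of both blocks. A block end supports at most one
full link (its boundary positions form one set), so paths are unique and
partition the blocks; a hypothetical cycle of full links — impossible for
linear genomes, since some genome must terminate the run — would be cut
deterministically. Genome termini bound paths by construction.

A path is reported as a **visiting block** for a flanking pair
`(b0, b_next)` when at least one traversal enters from `b0`, every
traversal entering from `b0` exits into `b_next`, and vice versa, with
both flanks outside the path. This is the definitional, model-level
check; note that it can fire on duplication-free instances (two unrelated
contexts aligned through one block), which is exactly the spurious-
similarity situation the detector exists for.

Genome-alignment cycles are enumerated as simple mixed cycles of the
Enredo structure (direction ignored for existence), requiring at least one
adjacency edge, at least two edges in total, and pairwise distinct
adjacency classes along the cycle — the last condition excludes plain
adjacent block pairs. Palindromes (single adjacency-edge loops at one
block end) are detected separately as head–head / tail–tail
self-adjacencies; direct tandem repeats (head–tail) are not palindromes.
Whirl/bulge/composite classification counts sign runs of the adjacency
directions around the cycle (0 changes = whirl, 2 = bulge, more =
composite) after applying the chosen genome orientations; the maximal-
colinear-path count of a cycle is orientation-invariant. The "short"
cycle length threshold is a parameter with no universal default; passing
`None` disables it.

## Modifications and segmentation

All four modifications act on the block set; graph effects are realized by
rebuilding, keeping a single source of truth. Splitting accepts any proper
nonempty segment subset (size-1 results allowed). Merging parallel blocks
takes an explicit relative-orientation flag, since the implied alignment
of the two segment sets is not determined by the block set itself.
Merging consecutive blocks requires a breakpoint-free adjacency between
equal-sized blocks; the adjacency positions pair the segments uniquely,
and orientation-discordant (head–head / tail–tail) full adjacencies are
concatenated after flipping one block's representation. Cutting an
adjacency records one breakpoint position per segment and never touches
the blocks; cut sets only grow. The final segmentation bounds segments by
the breakpoints of maximal colinear paths, the explicit cuts, and the
genome termini. No elimination schedule is built in: the pipeline command
exposes single steps plus a bounded iteration loop with an explicit cap,
since elimination of one substructure can create others and no global
termination claim is made.

## Synthetic data

The generator emulates the output of a local-alignment stage: a
ground-truth tiling with planted events. It starts from a colinear chain
of `n_blocks` blocks (default 8, lengths uniform in 2..12 bp — short on
purpose, the graphs depend only on segment structure) across `n_genomes`
(default 3). Per non-reference genome and block, an inversion, a
duplication and a translocation are planted as independent Bernoulli
events (defaults 0; tests state their rates explicitly), in that order.
Duplications choose uniformly among tandem, inverted-tandem (palindrome)
and dispersed placement. Genome 0 is an untouched reference, so an
inversion always yields a mixed-orientation block and a duplication always
yields an oversized block; dispersed insertions and translocations never
land inside a planted tandem/palindrome pair, so every planted palindrome
remains an adjacent inverted pair. These guarantees are what make the
sensitivity-1.0 recovery checks meaningful: they verify detector
correctness against a known ground truth, not detection power on real
data. Real local alignments bring overlap, partial homology, gapped
blocks and alignment errors, none of which the generator models; passing
tests therefore say nothing about aligner accuracy on real genomes.

Random sequence content is attached so the FASTA output is well-formed and
block lengths are consistent; the graphs themselves never read it.

## Problem sizes

Tests and the acceptance script run on worked examples of ≤ 12 blocks and
on batches of 20–100 seeded simulations with 5–8 blocks and 3 genomes —
sizes chosen so every claim can also be checked against brute-force
oracles (permutation search for colinearity, cut enumeration for
3-edge-connectivity, cycle enumeration for chains). The library itself
has no such limits, but the enumerator's caps and the quadratic
3-edge-connectivity step make "desk scale" its intended regime.

## Known limitations

- Blocks carry no column-level alignment detail; gapped blocks are
  accepted but never inspected internally.
- Raw, overlapping local alignments are out of scope: inputs must already
  tile the genomes (overlap trimming / segment-match refinement belongs to
  a preprocessing stage).
- A single shared origin joins all genome starts and ends in the cactus
  graph; per-genome telomere vertices are not modelled.
- `enumerate_consistent` requires every genome to contribute at least one
  adjacency edge (single-segment genomes are invisible to structures).
- No optimization objectives or automatic parameter selection for choosing
  modifications; the pipeline applies user-configured policies only.
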