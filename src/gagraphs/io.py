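"""Readers and writers: the block TSV interchange format, FASTA genome
lengths, BED segmentation output, and deterministic DOT exports of the four
graph structures."""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from .abruijn import ABruijnModel
from .alignment_graph import AlignmentGraphModel, inv_labels_ag
from .cactus import CactusModel
from .core import Block, BlockSet, Segment, validate_tiling
from .enredo import EnredoModel
from .modifications import FinalSegment

__all__ = [
    "read_blocks",
    "write_blocks",
    "read_genome_lengths",
    "write_dot",
    "write_bed",
]

_TSV_COLUMNS = ["block_id", "genome", "start", "end", "strand"]

_PALETTE = [
    "crimson",
    "dodgerblue",
    "forestgreen",
    "darkorange",
    "purple",
    "teal",
    "goldenrod",
    "deeppink",
]


def read_genome_lengths(fasta_path: str | Path) -> dict[str, int]:
    """Sequence lengths from a FASTA file (only lengths are needed by the
    graphs)."""
    from Bio import SeqIO

    return {
        rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def read_blocks(
    tsv_path: str | Path,
    fasta_path: str | Path | None = None,
    genome_lengths: Mapping[str, int] | None = None,
) -> BlockSet:
    """Read a block set from the TSV interchange format.

    Columns: block_id, genome, start, end, strand (+/-), coordinates
    0-based half-open.  A '-' row becomes a segment with p > q.  Genome
    lengths come from the FASTA, from ``genome_lengths``, or, failing both,
    from the rightmost segment end per genome.  The result is validated as
    a tiling; violations are reported with the offending line numbers where
    possible.
    """
    if fasta_path is not None:
        lengths = dict(read_genome_lengths(fasta_path))
    elif genome_lengths is not None:
        lengths = dict(genome_lengths)
    else:
        lengths = {}
    segments: dict[str, list[Segment]] = {}
    with open(tsv_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if row[:5] == _TSV_COLUMNS:
                continue  # header
            if len(row) < 5:
                raise ValueError(f"line {lineno}: expected 5 columns")
            bid, genome, start_s, end_s, strand = row[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"line {lineno}: non-integer coordinates"
                ) from None
            if strand == "+":
                seg = Segment(genome, start, end)
            elif strand == "-":
                seg = Segment(genome, end, start)
            else:
                raise ValueError(
                    f"line {lineno}: strand must be '+' or '-', got {strand!r}"
                )
            segments.setdefault(bid, []).append(seg)
            if genome not in lengths:
                lengths[genome] = 0
            if genome_lengths is None and fasta_path is None:
                lengths[genome] = max(lengths[genome], seg.end)
    bs = BlockSet(lengths, [Block(b, ss) for b, ss in segments.items()])
    problems = validate_tiling(bs)
    if problems:
        raise ValueError("invalid tiling: " + "; ".join(problems))
    return bs


def write_blocks(bs: BlockSet, out: TextIO | str | Path) -> None:
    """Write the TSV interchange format (canonical representations,
    deterministic row order)."""
    close = False
    if not hasattr(out, "write"):
        out = open(out, "w", newline="")
        close = True
    try:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for b in bs.blocks:
            for s in b.canonical.segments:
                writer.writerow(
                    [b.id, s.genome, s.start, s.end, s.orientation]
                )
    finally:
        if close:
            out.close()


def write_bed(segments: Iterable[FinalSegment], out: TextIO | str | Path) -> None:
    """Final segmentation as 0-based BED: genome, start, end, then a
    segment id and the owning colinear-path id."""
    close = False
    if not hasattr(out, "write"):
        out = open(out, "w", newline="")
        close = True
    try:
        for i, seg in enumerate(
            sorted(segments, key=lambda s: (s.genome, s.start))
        ):
            out.write(
                f"{seg.genome}\t{seg.start}\t{seg.end}\tseg{i}\t"
                f"path{seg.path_index}\n"
            )
    finally:
        if close:
            out.close()


def _genome_colors(genomes: Iterable[str]) -> dict[str, str]:
    return {
        g: _PALETTE[i % len(_PALETTE)] for i, g in enumerate(sorted(genomes))
    }


def write_dot(model, show_dup_labels: bool = False) -> str:
    """Deterministic DOT text for any of the four graph models.

    Adjacency edges are colored per genome; block edges are gray (dashed in
    the alignment graph when the orientations across the edge differ);
    cactus vertices are annotated with the number of adjacencies they hold.
    """
    buf = _io.StringIO()
    if isinstance(model, AlignmentGraphModel):
        _dot_alignment(model, buf)
    elif isinstance(model, ABruijnModel):
        _dot_abruijn(model, buf, show_dup_labels)
    elif isinstance(model, EnredoModel):
        _dot_enredo(model, buf)
    elif isinstance(model, CactusModel):
        _dot_cactus(model, buf)
    else:
        raise TypeError(f"cannot export {type(model).__name__}")
    return buf.getvalue()


def _dot_alignment(m: AlignmentGraphModel, buf) -> None:
    colors = _genome_colors(m.genome_lengths)
    inv = inv_labels_ag(m)
    buf.write("digraph alignment_graph {\n")
    for v in sorted(m.structure.vertices):
        s = m.labels[v]
        buf.write(f'  "{v}" [label="{s.genome}:{s.start}-{s.end}{s.orientation}"];\n')
    for u, v in sorted(m.structure.adjacency_edges):
        g = m.labels[u].genome
        buf.write(f'  "{u}" -> "{v}" [color={colors[g]}];\n')
    for e in sorted(m.structure.block_edges, key=sorted):
        u, v = sorted(e)
        style = "dashed" if inv[u] != inv[v] else "solid"
        buf.write(
            f'  "{u}" -> "{v}" [dir=none, color=gray, style={style}];\n'
        )
    buf.write("}\n")


def _dot_abruijn(m: ABruijnModel, buf, show_dup: bool) -> None:
    colors = _genome_colors(m.genome_lengths)
    from .abruijn import build_abruijn  # labels for colors need the genome

    buf.write("digraph abruijn_graph {\n")
    for v in sorted(m.structure.vertices):
        buf.write(f'  "{v}" [label="{v} (size {m.labels[v].size})"];\n')
    # recover genome of each edge through a rebuild (edge ids are stable)
    from .abruijn import recover_blocks_ab

    _, dup, _ = build_abruijn(recover_blocks_ab(m))
    for eid in sorted(m.structure.edges, key=lambda e: dup.rank.get(e, 0)):
        u, v = m.structure.edges[eid]
        g = dup.genome.get(eid)
        color = colors.get(g, "black")
        label = f', label="{dup.rank[eid]}"' if show_dup and eid in dup.rank else ""
        buf.write(f'  "{u}" -> "{v}" [color={color}{label}];\n')
    buf.write("}\n")


def _dot_enredo(m: EnredoModel, buf) -> None:
    colors = _genome_colors(m.genome_lengths)
    from .enredo import build_enredo, recover_blocks_en

    _, dup = build_enredo(recover_blocks_en(m))
    buf.write("digraph enredo_graph {\n")
    buf.write("  rankdir=LR;\n")
    for v in sorted(m.structure.vertices):
        buf.write(f'  "{v}";\n')
    for e in sorted(m.structure.block_edges, key=sorted):
        h = m.head_vertex[e]
        (t,) = set(e) - {h}
        buf.write(f'  "{t}" -> "{h}" [dir=none, color=black, penwidth=2];\n')
    for eid in sorted(m.structure.adjacency_edges):
        u, v = m.structure.adjacency_edges[eid]
        g = dup.genome.get(eid)
        color = colors.get(g, "black")
        buf.write(f'  "{u}" -> "{v}" [color={color}];\n')
    buf.write("}\n")


def _dot_cactus(m: CactusModel, buf) -> None:
    # count the adjacencies held by each cactus vertex: adjacency edges of
    # the retained Enredo model, mapped through the composed vertex map
    counts: dict[str, int] = {v: 0 for v in m.structure.vertices}
    for u, _w in m.enredo.structure.adjacency_edges.values():
        counts[m.vertex_map[u]] += 1
    buf.write("graph cactus_graph {\n")
    for v in sorted(m.structure.vertices):
        extra = ", shape=doublecircle" if v == m.structure.origin else ""
        buf.write(f'  "{v}" [label="{v} ({counts.get(v, 0)} adj)"{extra}];\n')
    for eid in sorted(m.structure.edges):
        u, w = m.structure.edges[eid]
        b = m.labels[eid]
        buf.write(f'  "{u}" -- "{w}" [label="{b.id}"];\n')
    buf.write("}\n")
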