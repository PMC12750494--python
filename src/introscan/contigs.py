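"""Haplotype-contig selection, concatenation and region mapping.

A candidate haplotype (e.g. a greenbug-resistance region absent from the
reference) is reconstructed by selecting assembled contigs whose reference
alignments fall inside a target window with adequate mapping quality,
concatenating them in reference order into one composite contig, and
tabulating how each composite region maps back onto the reference:
contig-side span, reference-side span, and the reference bases left
uncovered by aligned blocks (gaps).

Coordinates are 0-based half-open on both sides; spans are end - start.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence


@dataclass(frozen=True)
class ContigAlignment:
    """One contig-to-reference alignment record (PAF-like)."""

    contig_id: str
    contig_length: int
    target_id: str
    target_start: int
    target_end: int
    mapq: float
    strand: str = "+"
    aligned_block_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.target_start >= self.target_end:
            raise ValueError(
                f"{self.contig_id}: target interval "
                f"[{self.target_start}, {self.target_end}) is empty"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.contig_id}: bad strand {self.strand!r}")
        if sum(self.aligned_block_lengths) > self.target_end - self.target_start:
            raise ValueError(
                f"{self.contig_id}: aligned blocks exceed target span"
            )


class Window(NamedTuple):
    target_id: str
    start: int
    end: int


@dataclass(frozen=True)
class CompositeContig:
    """Ordered concatenation of selected contigs with cumulative offsets."""

    name: str
    members: tuple[str, ...]
    offsets: dict[str, tuple[int, int]]  # contig id -> (composite start, end)
    total_length: int


@dataclass(frozen=True)
class RegionMapping:
    """A composite-contig region and its reference-side footprint."""

    region_id: str
    contig_start: int
    contig_end: int
    ref_start: int
    ref_end: int
    contig_span: int
    ref_span: int
    gap: int


def select_contigs(
    alignments: Iterable[ContigAlignment], window: Window, mq_min: float = 20.0
) -> list[ContigAlignment]:
    """Keep alignments wholly inside the window with MQ strictly above mq_min.

    Both the alignment's target start and end must lie inside the window;
    contigs straddling a window boundary are dropped.  Input order is
    preserved.
    """
    if window.start >= window.end:
        raise ValueError(f"empty window [{window.start}, {window.end})")
    kept = []
    for aln in alignments:
        if (
            aln.target_id == window.target_id
            and aln.target_start >= window.start
            and aln.target_end <= window.end
            and aln.mapq > mq_min
        ):
            kept.append(aln)
    return kept


def build_composite(
    selected: Sequence[ContigAlignment], name: str = "composite"
) -> CompositeContig:
    """Concatenate contigs ordered by reference position.

    Contigs are sorted by target start (ties broken lexicographically by
    contig id); offsets are cumulative, so the composite length is the sum
    of member lengths.
    """
    if not selected:
        raise ValueError("no contigs to combine")
    ids = [a.contig_id for a in selected]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate contig id {dup!r}")
    ordered = sorted(selected, key=lambda a: (a.target_start, a.contig_id))
    offsets: dict[str, tuple[int, int]] = {}
    cursor = 0
    for aln in ordered:
        offsets[aln.contig_id] = (cursor, cursor + aln.contig_length)
        cursor += aln.contig_length
    return CompositeContig(
        name=name,
        members=tuple(a.contig_id for a in ordered),
        offsets=offsets,
        total_length=cursor,
    )


class RegionAlignment(NamedTuple):
    """Alignment of one composite-contig region back to the reference."""

    region_id: str
    contig_start: int
    contig_end: int
    ref_start: int
    ref_end: int
    aligned_block_lengths: tuple[int, ...]


def map_regions(regions: Iterable[RegionAlignment]) -> list[RegionMapping]:
    """Compute spans and reference gaps for composite-contig regions.

    Spans are end - start on each side.  The gap is the portion of the
    reference span not covered by aligned blocks — it depends on alignment
    detail, not on the difference of the two spans.  Rows are ordered by
    contig start.
    """
    mappings = []
    for r in regions:
        contig_span = r.contig_end - r.contig_start
        ref_span = r.ref_end - r.ref_start
        aligned = sum(r.aligned_block_lengths)
        gap = ref_span - aligned
        if gap < 0:
            raise ValueError(
                f"{r.region_id}: aligned blocks ({aligned} bp) exceed reference "
                f"span ({ref_span} bp)"
            )
        mappings.append(
            RegionMapping(
                region_id=r.region_id,
                contig_start=r.contig_start,
                contig_end=r.contig_end,
                ref_start=r.ref_start,
                ref_end=r.ref_end,
                contig_span=contig_span,
                ref_span=ref_span,
                gap=gap,
            )
        )
    mappings.sort(key=lambda m: m.contig_start)
    return mappings


# ---------------------------------------------------------------------------
# PAF I/O
# ---------------------------------------------------------------------------

def write_paf(alignments: Iterable[ContigAlignment], path: str | Path) -> None:
    """Write alignments in the minimal 12-column PAF layout.

    Query coordinates are emitted as the full contig; residue matches are
    the summed aligned block lengths; block length is the target span.
    """
    with open(path, "w") as fh:
        for a in alignments:
            matches = sum(a.aligned_block_lengths) or (a.target_end - a.target_start)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.contig_id,
                        a.contig_length,
                        0,
                        a.contig_length,
                        a.strand,
                        a.target_id,
                        a.target_end,  # placeholder target length >= end
                        a.target_start,
                        a.target_end,
                        matches,
                        a.target_end - a.target_start,
                        int(a.mapq),
                    )
                )
                + "\n"
            )


def read_paf(path: str | Path) -> list[ContigAlignment]:
    """Parse 12+ column PAF records into contig alignments."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected >=12 PAF columns")
            out.append(
                ContigAlignment(
                    contig_id=fields[0],
                    contig_length=int(fields[1]),
                    strand=fields[4],
                    target_id=fields[5],
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    mapq=float(fields[11]),
                    aligned_block_lengths=(int(fields[9]),),
                )
            )
    return out
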