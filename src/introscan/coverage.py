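"""Coverage summary tables and binned depth tracks.

The central currency of the presence/absence detectors is the per-sequence
coverage summary produced by ``samtools coverage`` (one row per reference
sequence: mapped reads, covered bases, breadth, mean depth, mean base
quality, mean mapping quality) together with fixed-width binned read-count
or depth tracks along each sequence.

Coordinate conventions: coverage tables use 1-based inclusive positions
(the samtools dialect); bedgraph tracks use 0-based half-open intervals.
All conversion happens at the I/O boundary; bins are 0-based internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COVERAGE_COLUMNS = (
    "#rname",
    "startpos",
    "endpos",
    "numreads",
    "covbases",
    "coverage",
    "meandepth",
    "meanbaseq",
    "meanmapq",
)


@dataclass(frozen=True)
class CoverageRecord:
    """Per-sequence alignment summary for one line against one reference.

    Positions are 1-based inclusive.  ``coverage`` is breadth as a
    percentage in [0, 100]; ``meandepth`` is mean reads per base.
    """

    rname: str
    startpos: int
    endpos: int
    numreads: int
    covbases: int
    coverage: float
    meandepth: float
    meanbaseq: float
    meanmapq: float

    def __post_init__(self) -> None:
        span = self.endpos - self.startpos + 1
        if span <= 0:
            raise ValueError(f"{self.rname}: empty span {self.startpos}-{self.endpos}")
        if self.covbases < 0 or self.covbases > span:
            raise ValueError(
                f"{self.rname}: covbases {self.covbases} outside [0, {span}]"
            )
        if self.numreads < 0:
            raise ValueError(f"{self.rname}: negative numreads")
        expected = 100.0 * self.covbases / span
        if abs(self.coverage - expected) > 0.01:
            raise ValueError(
                f"{self.rname}: coverage {self.coverage} inconsistent with "
                f"covbases/span ({expected:.4f})"
            )

    @property
    def span(self) -> int:
        return self.endpos - self.startpos + 1


@dataclass
class BinnedTrack:
    """Fixed-width bins of read counts or mean depths along one sequence.

    ``values[i]`` covers bases ``[i * bin_size, min((i+1) * bin_size, seq_length))``
    in 0-based coordinates; the final bin may be partial.
    """

    rname: str
    bin_size: int
    seq_length: int
    values: np.ndarray
    value_kind: str = "reads"  # "reads" or "depth"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_expected = math.ceil(self.seq_length / self.bin_size)
        if len(self.values) != n_expected:
            raise ValueError(
                f"{self.rname}: {len(self.values)} bins, expected {n_expected} "
                f"for length {self.seq_length} at bin size {self.bin_size}"
            )
        if (self.values < 0).any():
            raise ValueError(f"{self.rname}: negative bin values")
        if self.value_kind not in ("reads", "depth"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def n_bins(self) -> int:
        return len(self.values)


def bin_read_starts(
    positions: Sequence[int], bin_size: int, seq_length: int, rname: str = "seq"
) -> BinnedTrack:
    """Bin 1-based read start positions into fixed-width bins.

    A read starting at position ``pos`` falls in bin ``(pos - 1) // bin_size``;
    the sum over bins equals the number of reads.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = math.ceil(seq_length / bin_size)
    counts = np.zeros(n_bins, dtype=float)
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size:
        if pos.min() < 1 or pos.max() > seq_length:
            bad = pos[(pos < 1) | (pos > seq_length)][0]
            raise ValueError(f"read start {bad} outside [1, {seq_length}]")
        idx = (pos - 1) // bin_size
        np.add.at(counts, idx, 1.0)
    return BinnedTrack(rname=rname, bin_size=bin_size, seq_length=seq_length, values=counts)


def chromosome_breadth(record: CoverageRecord) -> float:
    """Fraction of the sequence covered by at least one read, in [0, 1]."""
    return record.covbases / record.span


def line_baseline(
    records: Iterable[CoverageRecord], exclude: frozenset | set | None = None
) -> float:
    """Genome-wide breadth baseline for one line.

    Unweighted mean of per-chromosome breadth over all sequences not in
    ``exclude``.  A whole-chromosome loss (e.g. a translocated arm) is
    detected as a drop of the target chromosome below this baseline.
    """
    exclude = exclude or set()
    breadths = [chromosome_breadth(r) for r in records if r.rname not in exclude]
    if not breadths:
        raise ValueError("no sequences left after exclusion")
    return float(np.mean(breadths))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_coverage_table(path: str | Path) -> list[CoverageRecord]:
    """Read a 9-column samtools-coverage TSV into records.

    The header row must begin with ``#rname``.  Invariants (covbases within
    span, coverage consistent) are enforced per record.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "#rname":
            raise ValueError(f"{path}: missing '#rname' header")
        records = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            try:
                rec = CoverageRecord(
                    rname=fields[0],
                    startpos=int(fields[1]),
                    endpos=int(fields[2]),
                    numreads=int(fields[3]),
                    covbases=int(fields[4]),
                    coverage=float(fields[5]),
                    meandepth=float(fields[6]),
                    meanbaseq=float(fields[7]),
                    meanmapq=float(fields[8]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_coverage_table(records: Iterable[CoverageRecord], path: str | Path) -> None:
    rows = [
        (
            r.rname,
            r.startpos,
            r.endpos,
            r.numreads,
            r.covbases,
            f"{r.coverage:.4g}",
            f"{r.meandepth:.4g}",
            f"{r.meanbaseq:.4g}",
            f"{r.meanmapq:.4g}",
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=COVERAGE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_bedgraph(tracks: Iterable[BinnedTrack], path: str | Path) -> None:
    """Write binned tracks as 4-column bedgraph (0-based half-open)."""
    with open(path, "w") as fh:
        for track in tracks:
            for i, v in enumerate(track.values):
                start = i * track.bin_size
                end = min(start + track.bin_size, track.seq_length)
                fh.write(f"{track.rname}\t{start}\t{end}\t{v:g}\n")


def read_bedgraph(path: str | Path, value_kind: str = "reads") -> list[BinnedTrack]:
    """Read a bedgraph produced by :func:`write_bedgraph` back into tracks.

    Assumes uniform bin width per sequence (final bin may be partial).
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["rname", "start", "end", "value"])
    tracks = []
    for rname, grp in df.groupby("rname", sort=False):
        grp = grp.sort_values("start")
        widths = (grp["end"] - grp["start"]).to_numpy()
        bin_size = int(widths[0]) if len(widths) == 1 else int(widths[:-1].max())
        seq_length = int(grp["end"].iloc[-1])
        tracks.append(
            BinnedTrack(
                rname=str(rname),
                bin_size=bin_size,
                seq_length=seq_length,
                values=grp["value"].to_numpy(),
                value_kind=value_kind,
            )
        )
    return tracks
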