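"""Synthetic wheat-like panel generator with known ground truth.

Emits everything the detectors consume — per-line coverage summaries,
binned read-count tracks, genotype matrices and contig alignment records —
for a panel of inbred lines sequenced at 5-20x and "aligned" to three
references:

* ``REF_MATCH``     — carries the introgressed segments (Jagger-like),
* ``REF_OTHER``     — lacks them (Chinese Spring-like) but includes the
                      assembled haplotype contig as an extra sequence,
* ``REF_COMPOSITE`` — ``REF_OTHER`` plus an alien (rye-like) chromosome.

Alignment is not simulated read-by-read.  Each bin of each sequence has an
*alignable fraction* f: the proportion of the bin homologous to the line's
genome (1 for matching sequence, a small conserved-homology fraction
``epsilon_conserved`` for alien sequence a line does not carry).  Mapped
reads per bin are Poisson with mean depth x alignable bases / read length;
covered bases follow the Lander-Waterman expectation
breadth = 1 - exp(-d) within the alignable part.  Mean MQ is drawn high
(~35) for true-homology alignments and low (~10) for conserved-sequence
pickup, and aggregated per sequence weighted by read count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

from .contigs import ContigAlignment, Window
from .coverage import BinnedTrack, CoverageRecord
from .variants import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING, Site

REF_MATCH = "REF_MATCH"
REF_OTHER = "REF_OTHER"
REF_COMPOSITE = "REF_COMPOSITE"
REFERENCES = (REF_MATCH, REF_OTHER, REF_COMPOSITE)


class IntrogressionSpec(NamedTuple):
    """One alien feature: where it sits and which lines carry it."""

    feature_id: str
    kind: Literal["segment", "translocation", "contig"]
    chrom: str
    interval: tuple[int, int]  # 0-based half-open, bp
    carriers: frozenset[str]


@dataclass(frozen=True)
class SimConfig:
    """Panel-level simulation parameters.

    Defaults emulate a Great-Plains-style panel: ~30 inbred lines at 5-20x
    depth, one alien segment on 2A, one whole-arm rye translocation on 1B
    and one haplotype contig, at one-tenth genome scale (desk-scale
    chromosomes, full-scale per-base statistics).
    """

    n_lines: int = 30
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "1A": 59_000_000,
            "1B": 68_000_000,
            "2A": 78_000_000,
            "3B": 83_000_000,
            "5A": 71_000_000,
            "7D": 64_000_000,
        }
    )
    bin_size: int = 1_000_000
    depth_range: tuple[float, float] = (5.0, 20.0)
    read_length: int = 150
    introgression_specs: tuple[IntrogressionSpec, ...] = ()
    epsilon_conserved: float = 0.01
    alien_arm_fraction: float = 0.3
    alien_chrom: str = "1R"
    alien_length: int = 53_300_000
    # haplotype contig (added to REF_OTHER / REF_COMPOSITE)
    contig_name: str = "tamGB3"
    contig_length: int = 2_800_000
    contig_bin_size: int = 50_000
    contig_regions: tuple[tuple[int, int], ...] = (
        (400_000, 500_000),
        (1_250_000, 1_350_000),
        (2_150_000, 2_250_000),
    )
    contig_source_chrom: str = "7D"
    contig_carrier_alignability: float = 0.9
    contig_noncarrier_alignability: float = 0.75
    # genotype model
    n_sites: int = 5_000
    het_error_rate: float = 0.01
    # contig-alignment generator
    contig_window: Window = Window("7D", 52_000_000, 64_000_000)
    n_true_contigs: int = 8
    n_decoy_contigs: int = 6
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be positive")
        if any(l <= 0 for l in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.bin_size <= 0 or self.read_length <= 0 or self.contig_bin_size <= 0:
            raise ValueError("bin_size and read_length must be positive")
        if not (0 <= self.epsilon_conserved < 1):
            raise ValueError("epsilon_conserved must be in [0, 1)")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth_range")
        for spec in self.introgression_specs:
            if spec.kind == "contig":
                length = self.contig_length
            else:
                if spec.chrom not in self.chromosome_lengths:
                    raise ValueError(f"{spec.feature_id}: unknown chromosome {spec.chrom}")
                length = self.chromosome_lengths[spec.chrom]
            s, e = spec.interval
            if not (0 <= s < e <= length):
                raise ValueError(f"{spec.feature_id}: interval outside chromosome")

    @property
    def line_ids(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_lines)]


def default_config(seed: int = 1, n_lines: int = 30) -> SimConfig:
    """The default study panel: 2NvS-like segment, 1RS-like translocation,
    Gb3-like contig haplotype, with fixed carrier sets."""
    lines = [f"L{i + 1:02d}" for i in range(n_lines)]
    specs = (
        IntrogressionSpec(
            "2NvS", "segment", "2A", (0, 3_300_000), frozenset(lines[0:6])
        ),
        IntrogressionSpec(
            "1RS", "translocation", "1B", (0, 16_000_000), frozenset(lines[6:11])
        ),
        IntrogressionSpec(
            "Gb3", "contig", "tamGB3", (0, 2_800_000), frozenset(lines[11:14])
        ),
    )
    return SimConfig(n_lines=n_lines, introgression_specs=specs, seed=seed)


@dataclass(frozen=True)
class TruthTable:
    """Ground truth: carrier flags per (line, feature) and per-line depth."""

    carriers: dict[tuple[str, str], bool]
    depths: dict[str, float]

    def is_carrier(self, line_id: str, feature_id: str) -> bool:
        return self.carriers[(line_id, feature_id)]


@dataclass(frozen=True)
class ReferenceSet:
    """Sequence names and lengths of the three simulated references."""

    sequences: dict[str, dict[str, int]]  # reference id -> rname -> length


def build_panel(config: SimConfig) -> tuple[ReferenceSet, TruthTable]:
    """Assemble reference descriptions and the ground-truth table.

    Rejects overlapping introgression intervals on one chromosome.
    Deterministic for a given seed.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for spec in config.introgression_specs:
        by_chrom.setdefault(spec.chrom, []).append((*spec.interval, spec.feature_id))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1, f1), (s2, e2, f2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(
                    f"features {f1} and {f2} overlap on chromosome {chrom}"
                )
    wheat = dict(config.chromosome_lengths)
    other = dict(wheat)
    other[config.contig_name] = config.contig_length
    composite = dict(other)
    composite[config.alien_chrom] = config.alien_length
    refs = ReferenceSet(
        sequences={REF_MATCH: wheat, REF_OTHER: other, REF_COMPOSITE: composite}
    )
    rng = np.random.default_rng([config.seed, 0])
    depths = {
        line: float(rng.uniform(*config.depth_range)) for line in config.line_ids
    }
    carriers = {
        (line, spec.feature_id): line in spec.carriers
        for line in config.line_ids
        for spec in config.introgression_specs
    }
    return refs, TruthTable(carriers=carriers, depths=depths)


# ---------------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------------

def _alignable_fractions(
    config: SimConfig,
    truth: TruthTable,
    line_id: str,
    reference_id: str,
    rname: str,
    length: int,
    bin_size: int,
) -> np.ndarray:
    """Per-bin fraction of the sequence homologous to the line's genome."""
    n_bins = math.ceil(length / bin_size)
    eps = config.epsilon_conserved

    def paint(frac: np.ndarray, start: int, end: int, value: float) -> None:
        for i in range(n_bins):
            b0, b1 = i * bin_size, min((i + 1) * bin_size, length)
            ov = max(0, min(end, b1) - max(start, b0))
            if ov:
                w = b1 - b0
                frac[i] = frac[i] * (w - ov) / w + value * ov / w

    if rname == config.alien_chrom:
        frac = np.full(n_bins, eps)
        carries_transloc = any(
            spec.kind == "translocation" and truth.is_carrier(line_id, spec.feature_id)
            for spec in config.introgression_specs
        )
        if carries_transloc:
            arm_end = int(config.alien_arm_fraction * length)
            paint(frac, 0, arm_end, 1.0)
        return frac

    if rname == config.contig_name:
        contig_spec = next(
            (s for s in config.introgression_specs if s.kind == "contig"), None
        )
        is_carrier = contig_spec is not None and truth.is_carrier(
            line_id, contig_spec.feature_id
        )
        bg = (
            config.contig_carrier_alignability
            if is_carrier
            else config.contig_noncarrier_alignability
        )
        frac = np.full(n_bins, bg)
        for start, end in config.contig_regions:
            paint(frac, start, end, 1.0 if is_carrier else eps)
        return frac

    frac = np.ones(n_bins)
    for spec in config.introgression_specs:
        if spec.chrom != rname or spec.kind == "contig":
            continue
        is_carrier = truth.is_carrier(line_id, spec.feature_id)
        start, end = spec.interval
        if spec.kind == "segment":
            # Segment present in REF_MATCH only: a mismatch between the
            # line's and the reference's haplotype leaves conserved pickup.
            ref_has = reference_id == REF_MATCH
            if is_carrier != ref_has:
                paint(frac, start, end, eps)
        elif spec.kind == "translocation":
            # No wheat reference carries the alien arm: carriers lose it.
            if is_carrier:
                paint(frac, start, end, eps)
    return frac


@dataclass
class PanelCoverage:
    """Coverage summaries and read-count tracks for one panel x reference."""

    reference_id: str
    records: dict[str, list[CoverageRecord]]  # line -> per-sequence records
    tracks: dict[str, dict[str, BinnedTrack]]  # line -> rname -> read counts

    def record(self, line_id: str, rname: str) -> CoverageRecord:
        for r in self.records[line_id]:
            if r.rname == rname:
                return r
        raise KeyError(f"{line_id}: no record for {rname}")


def reads_to_depth(track: BinnedTrack, read_length: int) -> BinnedTrack:
    """Convert a read-count track to mean-depth per bin."""
    widths = np.minimum(
        np.arange(1, track.n_bins + 1) * track.bin_size, track.seq_length
    ) - np.arange(track.n_bins) * track.bin_size
    return BinnedTrack(
        rname=track.rname,
        bin_size=track.bin_size,
        seq_length=track.seq_length,
        values=track.values * read_length / widths,
        value_kind="depth",
    )


def simulate_coverage(
    config: SimConfig, truth: TruthTable, reference_id: str
) -> PanelCoverage:
    """Simulate per-line coverage records and binned read-count tracks.

    Deterministic per (seed, line, reference, sequence): results do not
    depend on evaluation order.
    """
    if reference_id not in REFERENCES:
        raise ValueError(f"unknown reference {reference_id!r}")
    refs, _ = _refs_cached(config)
    seqs = refs.sequences[reference_id]
    ref_idx = REFERENCES.index(reference_id)
    records: dict[str, list[CoverageRecord]] = {}
    tracks: dict[str, dict[str, BinnedTrack]] = {}
    for li, line_id in enumerate(config.line_ids):
        depth = truth.depths[line_id]
        recs = []
        line_tracks = {}
        for si, (rname, length) in enumerate(sorted(seqs.items())):
            bin_size = (
                config.contig_bin_size if rname == config.contig_name else config.bin_size
            )
            rng = np.random.default_rng([config.seed, 1, li, ref_idx, si])
            frac = _alignable_fractions(
                config, truth, line_id, reference_id, rname, length, bin_size
            )
            n_bins = len(frac)
            widths = np.minimum(
                np.arange(1, n_bins + 1) * bin_size, length
            ) - np.arange(n_bins) * bin_size
            alignable = widths * frac
            lam = depth * alignable / config.read_length
            reads = rng.poisson(lam).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                local_depth = np.where(
                    alignable > 0, reads * config.read_length / np.maximum(alignable, 1e-12), 0.0
                )
            covbases = np.minimum(
                np.rint(alignable * (1.0 - np.exp(-local_depth))), widths
            ).astype(int)
            numreads = int(reads.sum())
            covb = int(covbases.sum())
            meandepth = numreads * config.read_length / length
            # read-weighted mean MQ: high for true homology, low for pickup
            high_reads = reads[frac > 0.5].sum()
            low_reads = reads[frac <= 0.5].sum()
            if numreads == 0:
                meanmapq = 0.0
            else:
                mq_high = float(np.clip(rng.normal(35.0, 1.5), 31.0, 45.0))
                mq_low = float(np.clip(rng.normal(10.0, 4.0), 0.0, 19.5))
                meanmapq = float(high_reads * mq_high + low_reads * mq_low) / numreads
            meanbaseq = float(np.clip(rng.normal(36.0, 0.5), 30.0, 42.0))
            recs.append(
                CoverageRecord(
                    rname=rname,
                    startpos=1,
                    endpos=length,
                    numreads=numreads,
                    covbases=covb,
                    coverage=round(100.0 * covb / length, 4),
                    meandepth=round(meandepth, 4),
                    meanbaseq=round(meanbaseq, 3),
                    meanmapq=round(meanmapq, 3),
                )
            )
            line_tracks[rname] = BinnedTrack(
                rname=rname,
                bin_size=bin_size,
                seq_length=length,
                values=reads,
                value_kind="reads",
            )
        records[line_id] = recs
        tracks[line_id] = line_tracks
    return PanelCoverage(reference_id=reference_id, records=records, tracks=tracks)


def _refs_cached(config: SimConfig) -> tuple[ReferenceSet, TruthTable]:
    return build_panel(config)


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenotypes:
    """Genotype matrix plus the per-site truth used to generate it."""

    matrix: GenotypeMatrix
    true_alt_freq: np.ndarray  # per-site allele frequency drawn from the spectrum


def simulate_genotypes(config: SimConfig, truth: TruthTable) -> SimulatedGenotypes:
    """Draw a biallelic genotype matrix for the inbred panel.

    Per-site true alternate-allele frequency is uniform on (0, 0.5]; each
    inbred line is homozygous alternate with that probability.  A genotype
    is replaced by a heterozygous error with probability
    ``het_error_rate`` and by a missing call with probability
    exp(-depth/2), emulating missingness growing as depth shrinks.
    """
    if config.n_lines < 2:
        raise ValueError("need at least two lines")
    rng = np.random.default_rng([config.seed, 2])
    chroms = sorted(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    n = config.n_sites
    chrom_idx = rng.choice(len(chroms), size=n, p=probs)
    bases = np.array(list("ACGT"))
    sites: list[Site] = []
    for i in range(n):
        chrom = chroms[chrom_idx[i]]
        pos = int(rng.integers(1, config.chromosome_lengths[chrom]))
        kind = rng.random()
        ref_b, alt_b = rng.choice(4, size=2, replace=False)
        if kind < 0.9:
            ref, alt = bases[ref_b], bases[alt_b]
        elif kind < 0.95:
            ref = bases[ref_b]
            alt = ref + "".join(rng.choice(bases, size=int(rng.integers(1, 4))))
        else:
            ref = bases[ref_b] + "".join(rng.choice(bases, size=int(rng.integers(1, 4))))
            alt = ref[0]
        sites.append(Site(chrom, pos, str(ref), str(alt)))
    sites.sort(key=lambda s: (s.chrom, s.pos))

    p = rng.uniform(0.0, 0.5, size=n)
    p = np.nextafter(p, 1.0)  # open at 0, closed at 0.5
    depths = np.array([truth.depths[l] for l in config.line_ids])
    miss_p = np.exp(-depths / 2.0)
    gt = np.where(
        rng.random((n, config.n_lines)) < p[:, None], HOM_ALT, HOM_REF
    ).astype(np.int8)
    het_mask = rng.random((n, config.n_lines)) < config.het_error_rate
    gt[het_mask] = HET
    miss_mask = rng.random((n, config.n_lines)) < miss_p[None, :]
    gt[miss_mask] = MISSING
    matrix = GenotypeMatrix(sites, config.line_ids, gt)
    return SimulatedGenotypes(matrix=matrix, true_alt_freq=p)


# ---------------------------------------------------------------------------
# Contig-alignment simulation
# ---------------------------------------------------------------------------

class LabelledAlignment(NamedTuple):
    alignment: ContigAlignment
    is_haplotype: bool


def simulate_contig_alignments(config: SimConfig) -> list[LabelledAlignment]:
    """Generate haplotype contigs plus decoys with truth labels.

    True contigs land wholly inside the configured target window with MQ
    above 20; decoys are either outside the window or inside at MQ <= 20.
    A record is labelled part of the haplotype exactly when it is
    in-window with MQ > 20.
    """
    rng = np.random.default_rng([config.seed, 3])
    win = config.contig_window
    target_len = config.chromosome_lengths[win.target_id]
    out: list[LabelledAlignment] = []

    def make(i: int, in_window: bool, high_mq: bool) -> ContigAlignment:
        length = int(rng.integers(50_000, 500_000))
        if in_window:
            start = int(rng.integers(win.start, max(win.start + 1, win.end - length)))
            end = min(start + length, win.end)
        else:
            start = int(rng.integers(0, max(1, win.start - length)))
            end = start + length
        mq = float(rng.uniform(30, 60)) if high_mq else float(rng.uniform(0, 20))
        span = end - start
        blocks = tuple(
            int(b)
            for b in np.diff(
                np.sort(rng.integers(0, span + 1, size=4)), prepend=0
            )[:2]
            if b > 0
        ) or (span,)
        return ContigAlignment(
            contig_id=f"ctg{i:03d}",
            contig_length=length,
            target_id=win.target_id,
            target_start=start,
            target_end=end,
            mapq=mq,
            strand="+" if rng.random() < 0.5 else "-",
            aligned_block_lengths=blocks,
        )

    idx = 0
    for _ in range(config.n_true_contigs):
        aln = make(idx, in_window=True, high_mq=True)
        out.append(LabelledAlignment(aln, True))
        idx += 1
    for k in range(config.n_decoy_contigs):
        if k % 2 == 0:
            aln = make(idx, in_window=False, high_mq=True)
        else:
            aln = make(idx, in_window=True, high_mq=False)
        out.append(LabelledAlignment(aln, False))
        idx += 1
    return out
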