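"""Presence-absence calling of alien introgressions from coverage evidence.

Three complementary decision procedures, each driven by a different
coverage signature of alien chromatin:

* **Cross-reference segment test** — a line carrying an alien segment that
  is present in one reference but not another gains whole-chromosome
  breadth when aligned to the reference that contains it (the 2NvS
  signature on wheat chromosome 2A: roughly +2 percentage points against a
  carrier reference, a decrease for non-carriers).

* **Arm-loss plus alien-chromosome validation** — a whole-arm translocation
  (1AL:1RS / 1BL:1RS) removes ~a fifth to a quarter of a wheat chromosome,
  so its breadth drops well below the line's genome-wide baseline
  (observed ~23%); alignment to a composite reference carrying the alien
  chromosome then validates the call: carriers reach ~30% breadth of the
  rye chromosome at high mapping quality, non-carriers stay under 2%
  breadth and under 1x mean depth, at low MQ.

* **Haplotype-contig test** — for a haplotype represented only by an
  assembled contig added to the reference, carriers show a small coverage
  change between the contig and its source chromosome region (~10%),
  non-carriers a large drop (~30%); carrier-specific regions inside the
  contig are located by a binned carrier/non-carrier depth ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coverage import BinnedTrack, CoverageRecord, chromosome_breadth, line_baseline

PRESENT = "present"
ABSENT = "absent"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PAVThresholds:
    """Decision thresholds for all three detectors.

    Defaults are anchored to the observed coverage signatures of known
    carriers: the ~2 percentage-point 2A gain, the ~23% chromosome-breadth
    drop of 1RS carriers (cutoff placed at 15%, between carrier drops and
    noise), the ~30% vs <2% rye-chromosome breadth split (present cutoff at
    20% for margin), the <1x non-carrier mean depth, the MQ > 30 carrier /
    MQ > 20 retention gates, and the ~10% vs ~30% contig-coverage split
    (boundary at 20%).
    """

    delta_pp_min: float = 2.0          # percentage points, cross-ref gain
    drop_rel_min: float = 0.15         # relative breadth drop vs baseline
    alien_present_breadth_min: float = 20.0   # % breadth of alien chromosome
    alien_absent_breadth_max: float = 2.0     # %
    alien_absent_depth_max: float = 1.0       # x
    mq_present_min: float = 30.0
    mq_filter_min: float = 20.0
    region_ratio_min: float = 5.0      # carrier/non-carrier depth ratio
    region_carrier_depth_min: float = 2.0  # x
    region_merge_gap: int = 1          # bins
    region_min_len: int = 1            # bins
    contig_change_boundary: float = 20.0   # % coverage change

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.alien_absent_breadth_max >= self.alien_present_breadth_min:
            raise ValueError("absent breadth ceiling must be below present floor")


@dataclass(frozen=True)
class PAVCall:
    """One presence/absence decision with its supporting evidence."""

    line_id: str
    feature_id: str
    status: str
    evidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in (PRESENT, ABSENT, AMBIGUOUS):
            raise ValueError(f"bad status {self.status!r}")
        for k, v in self.evidence.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite evidence {k}={v}")


def call_segment_pav_cross_ref(
    record_carrier_ref: CoverageRecord,
    record_other_ref: CoverageRecord,
    thresholds: PAVThresholds = PAVThresholds(),
    line_id: str = "",
    feature_id: str = "segment",
) -> PAVCall:
    """Cross-reference whole-chromosome breadth comparison.

    ``delta_pp`` is the breadth of the homologous chromosome against the
    carrier reference minus the breadth against the other reference, in
    percentage points.  A gain of at least ``delta_pp_min`` calls the
    segment present; any decrease calls it absent; small gains are
    ambiguous.
    """
    delta_pp = record_carrier_ref.coverage - record_other_ref.coverage
    if delta_pp >= thresholds.delta_pp_min:
        status = PRESENT
    elif delta_pp < 0:
        status = ABSENT
    else:
        status = AMBIGUOUS
    return PAVCall(line_id, feature_id, status, {"delta_pp": delta_pp})


def call_arm_loss(
    records: Sequence[CoverageRecord],
    target_chrom: str,
    thresholds: PAVThresholds = PAVThresholds(),
    line_id: str = "",
    feature_id: str = "translocation",
) -> PAVCall:
    """Whole-arm loss screen: target chromosome breadth vs line baseline.

    The baseline is the unweighted mean breadth over all other
    chromosomes; a relative drop of at least ``drop_rel_min`` flags a
    candidate translocation.
    """
    target = next((r for r in records if r.rname == target_chrom), None)
    if target is None:
        raise ValueError(f"target chromosome {target_chrom!r} not among records")
    baseline = line_baseline(records, exclude={target_chrom})
    if baseline == 0:
        raise ValueError("zero baseline breadth")
    relative_drop = (baseline - chromosome_breadth(target)) / baseline
    status = PRESENT if relative_drop >= thresholds.drop_rel_min else ABSENT
    return PAVCall(
        line_id,
        feature_id,
        status,
        {"relative_drop": relative_drop, "baseline": baseline},
    )


def validate_alien_chromosome(
    record_alien: CoverageRecord,
    thresholds: PAVThresholds = PAVThresholds(),
    line_id: str = "",
    feature_id: str = "translocation",
) -> PAVCall:
    """Validate a translocation by coverage of the alien chromosome itself.

    Against a composite reference, carriers show substantial breadth of the
    alien chromosome at high mean MQ; non-carriers show only trace breadth
    (conserved-sequence pickup) at sub-1x depth.  Anything between is
    ambiguous.
    """
    breadth_pct = record_alien.coverage
    if (
        breadth_pct >= thresholds.alien_present_breadth_min
        and record_alien.meanmapq >= thresholds.mq_present_min
    ):
        status = PRESENT
    elif (
        breadth_pct < thresholds.alien_absent_breadth_max
        and record_alien.meandepth < thresholds.alien_absent_depth_max
    ):
        status = ABSENT
    else:
        status = AMBIGUOUS
    return PAVCall(
        line_id,
        feature_id,
        status,
        {
            "alien_breadth": breadth_pct,
            "alien_meandepth": record_alien.meandepth,
            "mean_mq": record_alien.meanmapq,
        },
    )


def find_differential_regions(
    tracks: Mapping[str, BinnedTrack],
    carriers: set[str] | frozenset[str],
    thresholds: PAVThresholds = PAVThresholds(),
    pseudocount: float = 0.1,
) -> list[tuple[int, int]]:
    """Locate carrier-specific regions on a contig from binned depth tracks.

    Per bin, the carrier-group mean depth is divided by the non-carrier
    mean (plus a pseudocount); bins qualify when the ratio reaches
    ``region_ratio_min`` and the carrier mean reaches
    ``region_carrier_depth_min``.  Qualifying bins separated by at most
    ``region_merge_gap`` non-qualifying bins are merged; regions shorter
    than ``region_min_len`` bins are dropped.  Returns half-open bin
    intervals in coordinate order.
    """
    carrier_ids = sorted(set(carriers) & set(tracks))
    other_ids = sorted(set(tracks) - set(carriers))
    if not carrier_ids or not other_ids:
        raise ValueError("need at least one carrier and one non-carrier track")
    grids = {(t.bin_size, t.n_bins, t.seq_length) for t in tracks.values()}
    if len(grids) != 1:
        raise ValueError("tracks are on different bin grids")
    carrier_mean = np.mean([tracks[i].values for i in carrier_ids], axis=0)
    other_mean = np.mean([tracks[i].values for i in other_ids], axis=0)
    ratio = carrier_mean / (other_mean + pseudocount)
    qualifies = (ratio >= thresholds.region_ratio_min) & (
        carrier_mean >= thresholds.region_carrier_depth_min
    )
    regions: list[tuple[int, int]] = []
    start = None
    gap = 0
    for i, q in enumerate(qualifies):
        if q:
            if start is None:
                start = i
            end = i + 1
            gap = 0
        elif start is not None:
            gap += 1
            if gap > thresholds.region_merge_gap:
                regions.append((start, end))
                start = None
                gap = 0
    if start is not None:
        regions.append((start, end))
    return [(s, e) for s, e in regions if e - s >= thresholds.region_min_len]


def compare_contig_vs_reference(
    record_contig: CoverageRecord,
    record_ref_region: CoverageRecord,
    thresholds: PAVThresholds = PAVThresholds(),
    line_id: str = "",
    feature_id: str = "contig-haplotype",
) -> PAVCall:
    """Haplotype call from contig vs source-region coverage change.

    Carriers cover the haplotype contig nearly as well as the reference
    region (small absolute change in breadth %); non-carriers show a large
    drop.  The call is present when the change is strictly below the
    boundary.
    """
    change = abs(record_ref_region.coverage - record_contig.coverage)
    status = PRESENT if change < thresholds.contig_change_boundary else ABSENT
    return PAVCall(line_id, feature_id, status, {"coverage_change": change})
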