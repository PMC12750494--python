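"""Genotype matrices, site filters and variant summary statistics.

Implements the standard post-calling steps for an inbred diploid panel:
variant-type classification, per-site minor-allele-frequency / missingness /
heterozygosity filtering, per-sample allele-class proportions, sequence
ontology (SO) impact classification, and per-chromosome-arm binning of
variant counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

# Genotype codes for a diploid biallelic site.
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_VALID_BASES = set("ACGT")


class Site(NamedTuple):
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    so_terms: tuple[str, ...] = ()


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid genotype codes with per-site alleles.

    ``genotypes`` is an int8 array of shape (n_sites, n_samples) over
    {HOM_REF, HET, HOM_ALT, MISSING}.
    """

    sites: list[Site]
    samples: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype grid {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        for s in self.sites:
            for allele in (s.ref, s.alt):
                if not allele or not set(allele) <= _VALID_BASES:
                    raise ValueError(f"invalid allele {allele!r} at {s.chrom}:{s.pos}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        sites = [s for s, k in zip(self.sites, keep) if k]
        return GenotypeMatrix(sites, list(self.samples), self.genotypes[keep])


@dataclass(frozen=True)
class FilterConfig:
    """Site-level filter thresholds.

    All thresholds are inclusive: a site passes with maf >= maf_min,
    missing fraction <= max_missing and het fraction <= max_het.
    """

    maf_min: float = 0.05
    max_missing: float = 0.10
    max_het: float = 0.10

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_missing", "max_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def classify_variant_type(ref: str, alt: str) -> str:
    """Classify a ref/alt allele pair as SNP, INS or DEL."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(alt) > len(ref):
        return "INS"
    if len(alt) < len(ref):
        return "DEL"
    raise ValueError(f"unsupported multi-nucleotide substitution {ref}>{alt}")


class SiteStats(NamedTuple):
    maf: float
    missing_frac: float
    het_frac: float


def site_stats(column: np.ndarray) -> SiteStats:
    """Minor-allele frequency, missingness and heterozygosity of one site.

    Allele counts come from non-missing diploid genotypes (hom-ref
    contributes 2 reference alleles, het 1+1, hom-alt 2 alternate).
    Missingness is over all samples; heterozygosity over called samples.
    Raises if every genotype is missing (MAF undefined).
    """
    column = np.asarray(column)
    n_total = column.size
    if n_total == 0:
        raise ValueError("empty genotype column")
    called = column[column != MISSING]
    n_called = called.size
    if n_called == 0:
        raise ValueError("all genotypes missing: MAF undefined")
    alt_alleles = int(np.sum(called))  # codes 0/1/2 are alt allele counts
    total_alleles = 2 * n_called
    alt_freq = alt_alleles / total_alleles
    maf = 1.0 - max(alt_freq, 1.0 - alt_freq)
    missing_frac = (n_total - n_called) / n_total
    het_frac = int(np.sum(called == HET)) / n_called
    return SiteStats(maf=maf, missing_frac=missing_frac, het_frac=het_frac)


def filter_sites(
    matrix: GenotypeMatrix, config: FilterConfig
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply MAF / missingness / heterozygosity filters site by site.

    Returns the filtered matrix and the surviving counts per variant type
    (SNP / INS / DEL).  Sites where all genotypes are missing are dropped.
    """
    gt = matrix.genotypes
    n_total = gt.shape[1]
    n_missing = np.sum(gt == MISSING, axis=1)
    n_called = n_total - n_missing
    alt = np.where(gt == MISSING, 0, gt).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), 0.0)
        maf = 1.0 - np.maximum(alt_freq, 1.0 - alt_freq)
        het_frac = np.where(
            n_called > 0, np.sum(gt == HET, axis=1) / np.maximum(n_called, 1), 1.0
        )
    missing_frac = n_missing / n_total
    keep = (
        (n_called > 0)
        & (maf >= config.maf_min)
        & (missing_frac <= config.max_missing)
        & (het_frac <= config.max_het)
    )
    filtered = matrix.subset_sites(keep)
    counts = {"SNP": 0, "INS": 0, "DEL": 0}
    for s in filtered.sites:
        counts[classify_variant_type(s.ref, s.alt)] += 1
    return filtered, counts


def sample_allele_summary(matrix: GenotypeMatrix):
    """Per-sample allele-class percentages over all sites.

    For each sample, the percentage of sites called heterozygous, missing,
    homozygous reference and homozygous alternate; the four classes
    partition 100%.  Returns a pandas DataFrame indexed by sample id.
    """
    import pandas as pd

    if matrix.n_sites == 0:
        raise ValueError("no sites")
    gt = matrix.genotypes
    n = matrix.n_sites
    data = {
        "pct_het": 100.0 * np.sum(gt == HET, axis=0) / n,
        "pct_missing": 100.0 * np.sum(gt == MISSING, axis=0) / n,
        "pct_ref": 100.0 * np.sum(gt == HOM_REF, axis=0) / n,
        "pct_homalt": 100.0 * np.sum(gt == HOM_ALT, axis=0) / n,
    }
    return pd.DataFrame(data, index=list(matrix.samples))


# ---------------------------------------------------------------------------
# SO-term impact classification
# ---------------------------------------------------------------------------

IMPACT_ORDER = ("HIGH", "MODERATE", "LOW", "MODIFIER")

# Ensembl/snpEff-style putative impact per sequence ontology term.
DEFAULT_IMPACT_TABLE: dict[str, str] = {
    # HIGH: variants expected to disrupt protein function
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "frameshift_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "transcript_ablation": "HIGH",
    # MODERATE: non-disruptive changes that may alter effectiveness
    "missense_variant": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "disruptive_inframe_insertion": "MODERATE",
    "disruptive_inframe_deletion": "MODERATE",
    "protein_altering_variant": "MODERATE",
    # LOW: unlikely to change protein behaviour
    "synonymous_variant": "LOW",
    "splice_region_variant": "LOW",
    "incomplete_terminal_codon_variant": "LOW",
    "start_retained_variant": "LOW",
    "stop_retained_variant": "LOW",
    # MODIFIER: non-coding or positional annotations
    "intron_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
    "intergenic_region": "MODIFIER",
    "non_coding_transcript_variant": "MODIFIER",
    "non_coding_transcript_exon_variant": "MODIFIER",
    "5_prime_UTR_variant": "MODIFIER",
    "3_prime_UTR_variant": "MODIFIER",
}

DEFAULT_FUNCTIONAL_CLASSES: dict[str, str] = {
    "missense_variant": "missense",
    "stop_gained": "nonsense",
    "synonymous_variant": "silent",
    "stop_retained_variant": "silent",
    "start_retained_variant": "silent",
}


@dataclass
class ImpactTable:
    """SO term -> impact rating and functional class lookup."""

    impacts: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_IMPACT_TABLE))
    functional: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_FUNCTIONAL_CLASSES)
    )

    def __post_init__(self) -> None:
        bad = {v for v in self.impacts.values()} - set(IMPACT_ORDER)
        if bad:
            raise ValueError(f"unknown impact ratings {bad}")

    def classify_impact(self, so_terms: Sequence[str]) -> str:
        """Most severe impact among the site's SO terms (HIGH > ... > MODIFIER).

        Unknown terms default to MODIFIER with a warning.
        """
        best = len(IMPACT_ORDER) - 1
        for term in so_terms:
            if term not in self.impacts:
                warnings.warn(f"unknown SO term {term!r}; treating as MODIFIER")
                continue
            best = min(best, IMPACT_ORDER.index(self.impacts[term]))
        return IMPACT_ORDER[best]

    def functional_class(self, so_term: str) -> str:
        """missense / nonsense / silent / none for a single SO term."""
        return self.functional.get(so_term, "none")


def classify_impact(so_terms: Sequence[str], table: ImpactTable | None = None) -> str:
    return (table or ImpactTable()).classify_impact(so_terms)


def functional_class(so_term: str, table: ImpactTable | None = None) -> str:
    return (table or ImpactTable()).functional_class(so_term)


def bin_by_arm(
    sites: Iterable[Site], centromeres: Mapping[str, int]
) -> dict[str, int]:
    """Count sites per chromosome arm.

    Arm keys follow the convention ``"<chrom>.1"`` for the short arm (site
    position at or before the centromere) and ``"<chrom>.2"`` for the long
    arm.  Every chromosome seen must have a centromere entry.
    """
    counts: dict[str, int] = {}
    for s in sites:
        if s.chrom not in centromeres:
            raise KeyError(f"no centromere position for chromosome {s.chrom}")
        arm = ".1" if s.pos <= centromeres[s.chrom] else ".2"
        key = s.chrom + arm
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# VCF I/O (v4.2, GT-only FORMAT)
# ---------------------------------------------------------------------------

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a biallelic GT-only VCF v4.2; SO terms go into an ANN INFO key."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Sequence ontology terms">\n'
        )
        seen = {}
        for s in matrix.sites:
            seen.setdefault(s.chrom, 0)
            seen[s.chrom] = max(seen[s.chrom], s.pos)
        for chrom, length in seen.items():
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for s, row in zip(matrix.sites, matrix.genotypes):
            info = "ANN=" + ",".join(s.so_terms) if s.so_terms else "."
            gts = "\t".join(_GT_STRINGS[int(g)] for g in row)
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t{info}\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a genotype matrix via cyvcf2.

    Sites with more than one ALT allele are rejected: downstream counts are
    partitioned by variant type, which a multiallelic record would straddle.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[Site] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{rec.CHROM}:{rec.POS}: multiallelic records are not supported"
            )
        ann = rec.INFO.get("ANN")
        terms = tuple(ann.split(",")) if ann else ()
        sites.append(Site(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], terms))
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN/MISSING, 3=HOM_ALT
        gt_types = rec.gt_types
        row = np.full(len(samples), MISSING, dtype=np.int8)
        row[gt_types == 0] = HOM_REF
        row[gt_types == 1] = HET
        row[gt_types == 3] = HOM_ALT
        rows.append(row)
    vcf.close()
    genotypes = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(sites, samples, genotypes)
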