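import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_filter
from introscan.variants import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    FilterConfig,
    GenotypeMatrix,
    ImpactTable,
    Site,
    bin_by_arm,
    classify_variant_type,
    filter_sites,
    read_vcf,
    sample_allele_summary,
    site_stats,
    write_vcf,
)


def matrix_from(genotypes, types=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    types = types or ["SNP"] * genotypes.shape[0]
    alleles = {"SNP": ("A", "G"), "INS": ("A", "AT"), "DEL": ("ATG", "A")}
    sites = [
        Site("1A", 100 + i, *alleles[t]) for i, t in enumerate(types)
    ]
    samples = [f"S{j}" for j in range(genotypes.shape[1])]
    return GenotypeMatrix(sites, samples, genotypes)


class TestVariantType:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [("A", "G", "SNP"), ("A", "AT", "INS"), ("ATG", "A", "DEL")],
    )
    def test_classes(self, ref, alt, expected):
        assert classify_variant_type(ref, alt) == expected

    def test_mnp_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            classify_variant_type("AT", "GC")


class TestSiteStats:
    def test_single_het_below_maf3(self):
        col = np.array([HET] + [HOM_REF] * 29, dtype=np.int8)
        stats = site_stats(col)
        assert stats.maf == pytest.approx(1 / 60)
        assert stats.maf < 0.03

    def test_two_hom_alt_pass_maf5(self):
        col = np.array([HOM_ALT, HOM_ALT] + [HOM_REF] * 28, dtype=np.int8)
        assert site_stats(col).maf == pytest.approx(4 / 60)
        assert site_stats(col).maf > 0.05

    def test_monomorphic(self):
        col = np.array([HOM_REF] * 10, dtype=np.int8)
        stats = site_stats(col)
        assert stats == (0.0, 0.0, 0.0)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="missing"):
            site_stats(np.array([MISSING] * 5, dtype=np.int8))

    def test_denominators(self):
        # het over called samples, missing over all samples
        col = np.array([HET, MISSING, HOM_REF, HOM_REF], dtype=np.int8)
        stats = site_stats(col)
        assert stats.missing_frac == pytest.approx(0.25)
        assert stats.het_frac == pytest.approx(1 / 3)


class TestFilterSites:
    def test_inclusive_missing_boundary(self):
        base = [HOM_ALT] * 15 + [HOM_REF] * 15
        at_boundary = np.array([base[:27] + [MISSING] * 3])
        over = np.array([base[:26] + [MISSING] * 4])
        kept, _ = filter_sites(matrix_from(at_boundary), FilterConfig())
        assert kept.n_sites == 1
        kept, _ = filter_sites(matrix_from(over), FilterConfig())
        assert kept.n_sites == 0

    def test_no_thresholds_keeps_everything(self, rng):
        gt = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
        kept, _ = filter_sites(
            matrix_from(gt), FilterConfig(maf_min=0.0, max_missing=1.0, max_het=1.0)
        )
        assert kept.n_sites == 20

    def test_counts_partitioned_by_type(self):
        gt = np.tile([HOM_ALT] * 15 + [HOM_REF] * 15, (3, 1))
        _, counts = filter_sites(
            matrix_from(gt, types=["SNP", "INS", "DEL"]), FilterConfig()
        )
        assert counts == {"SNP": 1, "INS": 1, "DEL": 1}

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(10):
            gt = rng.choice(
                [HOM_REF, HET, HOM_ALT, MISSING],
                size=(50, 30),
                p=[0.62, 0.05, 0.3, 0.03],
            ).astype(np.int8)
            m = matrix_from(gt)
            for cfg in (FilterConfig(0.03), FilterConfig(0.05), FilterConfig(0.0, 0.5, 0.5)):
                kept, _ = filter_sites(m, cfg)
                expected = brute_force_filter(m, cfg)
                got_positions = {s.pos for s in kept.sites}
                exp_positions = {s.pos for s, k in zip(m.sites, expected) if k}
                assert got_positions == exp_positions

    @settings(derandomize=True, max_examples=30)
    @given(maf_lo=st.floats(0.0, 0.2), maf_delta=st.floats(0.0, 0.3), seed=st.integers(0, 100))
    def test_monotone_in_maf(self, maf_lo, maf_delta, seed):
        rng = np.random.default_rng(seed)
        gt = rng.choice(
            [HOM_REF, HET, HOM_ALT, MISSING], size=(40, 20), p=[0.6, 0.05, 0.3, 0.05]
        ).astype(np.int8)
        m = matrix_from(gt)
        lo, _ = filter_sites(m, FilterConfig(maf_min=maf_lo))
        hi, _ = filter_sites(m, FilterConfig(maf_min=min(maf_lo + maf_delta, 0.5)))
        assert hi.n_sites <= lo.n_sites


class TestSampleAlleleSummary:
    def test_all_hom_ref(self):
        gt = np.zeros((5, 3), dtype=np.int8)
        df = sample_allele_summary(matrix_from(gt))
        assert (df["pct_ref"] == 100.0).all()
        assert (df[["pct_het", "pct_missing", "pct_homalt"]] == 0.0).all().all()

    def test_enumerated_mix(self):
        gt = np.array([[HOM_REF], [HET], [MISSING], [HOM_ALT]], dtype=np.int8)
        df = sample_allele_summary(matrix_from(gt))
        row = df.iloc[0]
        assert row["pct_ref"] == row["pct_het"] == row["pct_missing"] == 25.0

    def test_partition_sums_to_100(self, rng):
        gt = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=(33, 7)).astype(np.int8)
        df = sample_allele_summary(matrix_from(gt))
        assert np.allclose(df.sum(axis=1), 100.0)


class TestImpact:
    def test_severity_classes(self):
        table = ImpactTable()
        assert table.classify_impact(["stop_gained"]) == "HIGH"
        assert table.classify_impact(["synonymous_variant"]) == "LOW"
        assert table.classify_impact(["intron_variant", "missense_variant"]) == "MODERATE"
        assert table.classify_impact(["intergenic_variant"]) == "MODIFIER"

    def test_unknown_term_warns_and_defaults_to_modifier(self):
        table = ImpactTable()
        with pytest.warns(UserWarning, match="unknown SO term"):
            assert table.classify_impact(["made_up_term"]) == "MODIFIER"

    @pytest.mark.parametrize(
        "term, expected",
        [
            ("missense_variant", "missense"),
            ("stop_gained", "nonsense"),
            ("synonymous_variant", "silent"),
            ("upstream_gene_variant", "none"),
        ],
    )
    def test_functional_class(self, term, expected):
        assert ImpactTable().functional_class(term) == expected


class TestArmBinning:
    def test_boundary_on_short_arm_and_conservation(self):
        sites = [Site("1A", p, "A", "G") for p in (10, 50, 51, 99)]
        counts = bin_by_arm(sites, {"1A": 50})
        assert counts == {"1A.1": 2, "1A.2": 2}
        assert sum(counts.values()) == len(sites)

    def test_missing_centromere_raises(self):
        with pytest.raises(KeyError, match="centromere"):
            bin_by_arm([Site("9Z", 1, "A", "G")], {"1A": 50})


class TestVcfIO:
    def test_round_trip(self, tmp_path):
        gt = np.array(
            [[HOM_REF, HET, MISSING], [HOM_ALT, HOM_REF, HOM_REF]], dtype=np.int8
        )
        sites = [
            Site("1A", 100, "A", "G", ("missense_variant",)),
            Site("2A", 5, "T", "TAC"),
        ]
        m = GenotypeMatrix(sites, ["s1", "s2", "s3"], gt)
        p = tmp_path / "panel.vcf"
        write_vcf(m, p)
        back = read_vcf(p)
        assert back.samples == m.samples
        assert back.sites == m.sites
        assert (back.genotypes == m.genotypes).all()
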