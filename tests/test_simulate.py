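import dataclasses
import math

import numpy as np
import pytest

import introscan as isc
from introscan.simulate import (
    REF_COMPOSITE,
    REF_MATCH,
    REF_OTHER,
    IntrogressionSpec,
    SimConfig,
    TruthTable,
    build_panel,
    default_config,
    simulate_contig_alignments,
    simulate_coverage,
    simulate_genotypes,
)


def small_config(**kw):
    defaults = dict(
        n_lines=4,
        chromosome_lengths={"1A": 5_000_000, "1B": 5_000_000, "2A": 5_000_000},
        bin_size=1_000_000,
        alien_length=5_000_000,
        contig_length=500_000,
        contig_regions=((100_000, 150_000),),
        contig_window=isc.simulate.Window("1A", 3_000_000, 5_000_000),
        n_sites=200,
        seed=7,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestBuildPanel:
    def test_no_introgressions_all_false(self):
        refs, truth = build_panel(small_config())
        assert truth.carriers == {}
        assert len(truth.depths) == 4

    def test_determinism(self):
        cfg = default_config(seed=5)
        a = build_panel(cfg)
        b = build_panel(cfg)
        assert a == b

    def test_truth_flags_match_specs(self):
        spec = IntrogressionSpec(
            "2NvS", "segment", "2A", (0, 1_000_000), frozenset({"L01", "L02"})
        )
        _, truth = build_panel(small_config(introgression_specs=(spec,)))
        flags = {l: truth.is_carrier(l, "2NvS") for l in ["L01", "L02", "L03", "L04"]}
        assert flags == {"L01": True, "L02": True, "L03": False, "L04": False}

    def test_overlapping_intervals_rejected(self):
        specs = (
            IntrogressionSpec("f1", "segment", "2A", (0, 2_000_000), frozenset()),
            IntrogressionSpec("f2", "translocation", "2A", (1_000_000, 3_000_000), frozenset()),
        )
        with pytest.raises(ValueError, match="overlap"):
            build_panel(small_config(introgression_specs=specs))

    def test_composite_reference_adds_alien_chromosome(self):
        refs, _ = build_panel(small_config())
        assert "1R" in refs.sequences[REF_COMPOSITE]
        assert "1R" not in refs.sequences[REF_OTHER]
        assert "1R" not in refs.sequences[REF_MATCH]


class TestSimulateCoverage:
    def test_unknown_reference_rejected(self):
        cfg = small_config()
        _, truth = build_panel(cfg)
        with pytest.raises(ValueError, match="unknown reference"):
            simulate_coverage(cfg, truth, "REF_NOPE")

    def test_zero_conserved_homology_gives_zero_alien_coverage(self):
        cfg = small_config(epsilon_conserved=0.0)
        _, truth = build_panel(cfg)
        pc = simulate_coverage(cfg, truth, REF_COMPOSITE)
        rec = pc.record("L01", "1R")  # no translocation feature: non-carrier
        assert rec.coverage == 0.0
        assert rec.meandepth == 0.0

    def test_carrier_alien_breadth_matches_lander_waterman(self):
        spec = IntrogressionSpec(
            "1RS", "translocation", "1B", (0, 1_500_000), frozenset({"L01"})
        )
        cfg = small_config(
            introgression_specs=(spec,),
            epsilon_conserved=0.0,
            alien_arm_fraction=0.3,
            depth_range=(12.0, 12.0),
        )
        _, truth = build_panel(cfg)
        pc = simulate_coverage(cfg, truth, REF_COMPOSITE)
        rec = pc.record("L01", "1R")
        expected = 30.0 * (1 - math.exp(-12.0))
        assert rec.coverage == pytest.approx(expected, abs=0.5)

    def test_read_counts_conserved_between_track_and_record(self):
        cfg = default_config(seed=3, n_lines=4)
        _, truth = build_panel(cfg)
        pc = simulate_coverage(cfg, truth, REF_OTHER)
        for line in cfg.line_ids:
            for rec in pc.records[line]:
                assert pc.tracks[line][rec.rname].values.sum() == rec.numreads

    def test_determinism(self):
        cfg = small_config()
        _, truth = build_panel(cfg)
        a = simulate_coverage(cfg, truth, REF_MATCH)
        b = simulate_coverage(cfg, truth, REF_MATCH)
        assert a.records == b.records

    def test_empirical_breadth_matches_model_over_bins(self):
        # at fixed depth d, per-bin covered fraction should be 1 - exp(-d)
        cfg = small_config(
            n_lines=1,
            chromosome_lengths={"1A": 100_000_000},
            bin_size=100_000,  # 1,000 bins
            depth_range=(4.0, 4.0),
        )
        _, truth = build_panel(cfg)
        pc = simulate_coverage(cfg, truth, REF_MATCH)
        rec = pc.record("L01", "1A")
        expected = 1 - math.exp(-4.0)
        n_bins = 1000
        # binomial-style tolerance: 3 SD of the mean over bins, plus Poisson
        # wobble of the per-bin depth
        sd = 3 * math.sqrt(expected * (1 - expected) / n_bins) + 0.01
        assert rec.covbases / rec.span == pytest.approx(expected, abs=sd)


class TestSimulateGenotypes:
    def test_limit_case_no_het_no_missing(self):
        cfg = small_config(het_error_rate=0.0, depth_range=(50.0, 50.0), n_sites=500)
        _, truth = build_panel(cfg)
        sg = simulate_genotypes(cfg, truth)
        assert not (sg.matrix.genotypes == 1).any()
        assert not (sg.matrix.genotypes == -1).any()

    def test_determinism(self):
        cfg = small_config()
        _, truth = build_panel(cfg)
        a = simulate_genotypes(cfg, truth)
        b = simulate_genotypes(cfg, truth)
        assert (a.matrix.genotypes == b.matrix.genotypes).all()
        assert a.matrix.sites == b.matrix.sites

    def test_missingness_matches_closed_form(self):
        cfg = small_config(n_lines=2, n_sites=10_000, het_error_rate=0.0)
        _, truth = build_panel(cfg)
        truth = TruthTable(carriers=truth.carriers, depths={"L01": 5.0, "L02": 5.0})
        sg = simulate_genotypes(cfg, truth)
        p_expected = math.exp(-2.5)
        observed = (sg.matrix.genotypes == -1).mean(axis=0)
        sd = math.sqrt(p_expected * (1 - p_expected) / 10_000)
        for obs in observed:
            assert obs == pytest.approx(p_expected, abs=3 * sd)

    def test_sites_sorted_and_alleles_valid(self):
        cfg = small_config()
        _, truth = build_panel(cfg)
        sg = simulate_genotypes(cfg, truth)
        keys = [(s.chrom, s.pos) for s in sg.matrix.sites]
        assert keys == sorted(keys)


class TestSimulateContigAlignments:
    def test_truth_labels_by_construction(self):
        cfg = small_config(n_true_contigs=5, n_decoy_contigs=6)
        labelled = simulate_contig_alignments(cfg)
        win = cfg.contig_window
        for aln, is_hap in labelled:
            in_window = (
                aln.target_id == win.target_id
                and aln.target_start >= win.start
                and aln.target_end <= win.end
            )
            assert is_hap == (in_window and aln.mapq > 20)

    def test_exactly_k_records_pass_window_and_mq(self):
        cfg = small_config(n_true_contigs=5, n_decoy_contigs=6)
        labelled = simulate_contig_alignments(cfg)
        n_pass = sum(
            1
            for aln, _ in labelled
            if aln.target_start >= cfg.contig_window.start
            and aln.target_end <= cfg.contig_window.end
            and aln.mapq > 20
        )
        assert n_pass == 5

    def test_no_decoys_all_high_mq_in_window(self):
        cfg = small_config(n_true_contigs=4, n_decoy_contigs=0)
        labelled = simulate_contig_alignments(cfg)
        assert all(is_hap for _, is_hap in labelled)
        assert all(aln.mapq > 20 for aln, _ in labelled)


class TestConfigValidation:
    def test_interval_outside_chromosome_rejected(self):
        spec = IntrogressionSpec("f", "segment", "2A", (0, 10_000_000), frozenset())
        with pytest.raises(ValueError, match="interval"):
            small_config(introgression_specs=(spec,))

    def test_bad_epsilon_rejected(self):
        with pytest.raises(ValueError, match="epsilon"):
            small_config(epsilon_conserved=1.0)

    def test_bad_depth_range_rejected(self):
        with pytest.raises(ValueError, match="depth_range"):
            small_config(depth_range=(10.0, 5.0))
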