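"""End-to-end orchestration: simulate, detect, filter, summarize.

Stages run in dependency order under a single seed; every output file is
listed in a JSON manifest with its SHA-256 digest, so a rerun with the
same configuration can be verified byte-for-byte on the TSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import contigs as ct
from . import coverage as cov
from . import diversity as dv
from . import pav
from . import simulate as sim
from . import variants as var

STAGES = ("simulate", "coverage", "pav", "contig", "vcfstats", "diversity")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def detect_panel(
    config: sim.SimConfig,
    truth: sim.TruthTable,
    thresholds: pav.PAVThresholds = pav.PAVThresholds(),
) -> pd.DataFrame:
    """Run all three detectors over the simulated panel.

    Returns one row per (line, feature) with the call and headline
    evidence.  Translocation calls combine the arm-loss screen with the
    alien-chromosome validation: present requires both, absent requires
    both negative, anything else is ambiguous.
    """
    cov_match = sim.simulate_coverage(config, truth, sim.REF_MATCH)
    cov_other = sim.simulate_coverage(config, truth, sim.REF_OTHER)
    cov_comp = sim.simulate_coverage(config, truth, sim.REF_COMPOSITE)
    rows = []
    for line in config.line_ids:
        for spec in config.introgression_specs:
            if spec.kind == "segment":
                call = pav.call_segment_pav_cross_ref(
                    cov_match.record(line, spec.chrom),
                    cov_other.record(line, spec.chrom),
                    thresholds,
                    line_id=line,
                    feature_id=spec.feature_id,
                )
            elif spec.kind == "translocation":
                wheat_only = [
                    r
                    for r in cov_other.records[line]
                    if r.rname in config.chromosome_lengths
                ]
                screen = pav.call_arm_loss(
                    wheat_only, spec.chrom, thresholds, line, spec.feature_id
                )
                valid = pav.validate_alien_chromosome(
                    cov_comp.record(line, config.alien_chrom),
                    thresholds,
                    line,
                    spec.feature_id,
                )
                if screen.status == valid.status:
                    status = screen.status
                else:
                    status = pav.AMBIGUOUS
                call = pav.PAVCall(
                    line,
                    spec.feature_id,
                    status,
                    {**screen.evidence, **valid.evidence},
                )
            else:  # contig haplotype
                call = pav.compare_contig_vs_reference(
                    cov_other.record(line, config.contig_name),
                    cov_other.record(line, config.contig_source_chrom),
                    thresholds,
                    line_id=line,
                    feature_id=spec.feature_id,
                )
            rows.append(
                {
                    "line_id": call.line_id,
                    "feature_id": call.feature_id,
                    "status": call.status,
                    "truth": truth.is_carrier(line, spec.feature_id),
                    **{f"ev_{k}": v for k, v in call.evidence.items()},
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: sim.SimConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
    thresholds: pav.PAVThresholds = pav.PAVThresholds(),
    filter_config: var.FilterConfig = var.FilterConfig(),
    pi_window: int = 1_000_000,
) -> dict:
    """Execute the selected stages and write an output manifest."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    refs, truth = sim.build_panel(config)

    if "simulate" in stages:
        truth_df = pd.DataFrame(
            [
                {
                    "line_id": line,
                    "feature_id": fid,
                    "carrier": truth.carriers[(line, fid)],
                    "depth": truth.depths[line],
                }
                for (line, fid) in sorted(truth.carriers)
            ]
        )
        p = outdir / "truth.tsv"
        truth_df.to_csv(p, sep="\t", index=False)
        outputs.append(p)

    panel = None
    if {"coverage", "pav"} & set(stages):
        panel = {r: sim.simulate_coverage(config, truth, r) for r in sim.REFERENCES}

    if "coverage" in stages:
        for ref_id, pc in panel.items():
            for line in config.line_ids:
                p = outdir / f"coverage_{ref_id}_{line}.tsv"
                cov.write_coverage_table(pc.records[line], p)
                outputs.append(p)
            bg = outdir / f"reads_{ref_id}.bedgraph"
            first_line = config.line_ids[0]
            cov.write_bedgraph(pc.tracks[first_line].values(), bg)
            outputs.append(bg)

    if "pav" in stages:
        calls = detect_panel(config, truth, thresholds)
        p = outdir / "pav_calls.tsv"
        calls.to_csv(p, sep="\t", index=False, float_format="%.6g")
        outputs.append(p)

    if "contig" in stages:
        labelled = sim.simulate_contig_alignments(config)
        paf = outdir / "contig_alignments.paf"
        ct.write_paf([l.alignment for l in labelled], paf)
        outputs.append(paf)
        selected = ct.select_contigs(
            [l.alignment for l in labelled],
            config.contig_window,
            thresholds.mq_filter_min,
        )
        composite = ct.build_composite(selected, name=config.contig_name)
        p = outdir / "composite_offsets.tsv"
        pd.DataFrame(
            [
                {"contig_id": cid, "start": s, "end": e}
                for cid, (s, e) in composite.offsets.items()
            ]
        ).to_csv(p, sep="\t", index=False)
        outputs.append(p)

    genos = None
    if {"vcfstats", "diversity"} & set(stages):
        genos = sim.simulate_genotypes(config, truth)

    if "vcfstats" in stages:
        raw_vcf = outdir / "panel_raw.vcf"
        var.write_vcf(genos.matrix, raw_vcf)
        outputs.append(raw_vcf)
        filtered, counts = var.filter_sites(genos.matrix, filter_config)
        fv = outdir / "panel_filtered.vcf"
        var.write_vcf(filtered, fv)
        outputs.append(fv)
        p = outdir / "variant_counts.tsv"
        pd.DataFrame([counts]).to_csv(p, sep="\t", index=False)
        outputs.append(p)
        p = outdir / "sample_allele_summary.tsv"
        var.sample_allele_summary(genos.matrix).to_csv(p, sep="\t")
        outputs.append(p)

    if "diversity" in stages:
        filtered, _ = var.filter_sites(genos.matrix, filter_config)
        tracks = dv.windowed_pi(filtered, pi_window, config.chromosome_lengths)
        p = outdir / "pi.bedgraph"
        with open(p, "w") as fh:
            for t in tracks:
                for i, v in enumerate(t.values):
                    start = i * t.window
                    end = min(start + t.window, t.seq_length)
                    fh.write(f"{t.chrom}\t{start}\t{end}\t{v:.8g}\n")
        outputs.append(p)
        dm = dv.ibs_distance_matrix(filtered)
        tree = dv.neighbor_joining(dm)
        p = outdir / "nj_tree.nwk"
        p.write_text(tree + "\n")
        outputs.append(p)

    manifest = {
        "seed": config.seed,
        "stages": list(stages),
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if isinstance(v, (int, float, str, bool))
        },
        "outputs": {str(p.name): _sha256(p) for p in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
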