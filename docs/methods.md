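# Methods

## Coverage model

The package consumes per-sequence coverage summaries (the nine-column
samtools-coverage layout, 1-based inclusive coordinates) and fixed-width
binned read-count tracks (bedgraph, 0-based half-open). Breadth of
coverage — the fraction of bases covered by at least one read — is the
primary statistic; mean depth and mean mapping quality are secondary
evidence. For sequence a line truly carries, breadth at mean depth *d* is
modelled by the Lander–Waterman expectation *1 − e^(−d)*; at panel depths
of 5–20× this saturates near 1, so breadth deficits measure missing
homology rather than shallow sequencing.

## Decision rules and thresholds

All thresholds live in `PAVThresholds` and are surfaced in the YAML
config.

| parameter | default | units | rationale |
|---|---|---|---|
| `delta_pp_min` | 2.0 | percentage points | observed whole-chromosome gain of segment carriers between references; gains below this are called ambiguous, decreases absent |
| `drop_rel_min` | 0.15 | fraction | carriers of a whole-arm translocation drop ~23% below baseline; 0.15 sits midway between carrier drops and noise |
| `alien_present_breadth_min` | 20 | % | carriers of a short-arm translocation cover ~30% of the alien chromosome; 20 keeps margin above the non-carrier class |
| `alien_absent_breadth_max` | 2 | % | non-carriers show only conserved-sequence pickup |
| `alien_absent_depth_max` | 1 | × | ditto, in depth |
| `mq_present_min` / `mq_filter_min` | 30 / 20 | MQ | carrier alignments are confident (mean MQ > 30); MQ ≤ 20 alignments would be removed by standard filtering |
| `region_ratio_min`, `region_carrier_depth_min` | 5, 2 | ratio, × | binned carrier/(non-carrier + 0.1) depth ratio; conservative against shared background |
| `contig_change_boundary` | 20 | % points | midpoint between the ~10% change of haplotype carriers and the ~30% drop of non-carriers |

The line baseline is the **unweighted** mean of per-chromosome breadths
(excluding the tested chromosome). A length-weighted mean differs by well
under the decision margin on realistic karyotypes; the flag is exposed by
passing pre-filtered record lists.

Ambiguous is a first-class outcome of the segment and alien-validation
rules: a call is only present/absent when the corresponding threshold
condition actually holds. The pipeline's combined translocation call
requires the arm-loss screen and the alien-chromosome validation to
agree; disagreement yields ambiguous rather than a forced decision.

## Composite-contig region mapping

Contigs are selected when their reference alignment lies wholly inside
the target window with MQ strictly greater than the gate, ordered by
target start (ties broken lexicographically by contig id) and
concatenated with cumulative offsets. Region rows report contig-side and
reference-side spans as `end − start` (0-based half-open on both sides)
— the convention that the published region coordinates satisfy exactly.
The reference **gap** is the reference span minus the summed aligned
block lengths: it depends on alignment detail and is *not* the
difference of the two spans. Negative gaps (blocks exceeding the span)
are rejected as inconsistent input.

## Variant filters and summaries

Site statistics use allele counts from called diploid genotypes only
(hom-ref → 2 ref, het → 1+1, hom-alt → 2 alt). MAF is `1 − max allele
frequency`; the missing fraction is over all samples; the het fraction is
over called samples (the latter two denominators are the natural choices
and are documented here because other conventions exist). Thresholds are
inclusive (`maf ≥ maf_min`, `missing ≤ 0.10`, `het ≤ 0.10`). A direct
consequence, verified in the acceptance suite: with 30 homozygous
samples a 5% MAF filter admits no site whose alternate allele occurs in
fewer than two individuals (one carrier contributes at most 2/60 ≈ 3.3%).
Multiallelic records are rejected at the VCF reader because the type
summaries (SNP/INS/DEL) partition sites. Sites with all genotypes
missing are dropped. The centromere position itself is assigned to the
short arm (`pos ≤ centromere → arm .1`) — an arbitrary, documented
tie-break.

## Diversity and trees

Per-site π uses the sample-size-corrected estimator
`n/(n−1) · (1 − Σ pᵢ²)` over called alleles, which equals the mean
pairwise difference over all allele pairs (asserted against brute-force
enumeration). Windowed per-base π divides window sums by the full window
width, counting invariant bases as zero contributions; the alternative
(callable-base denominator) is not implemented because variant records
carry no callability mask. The tree distance is identity-by-state:
`1 − mean(shared alleles / 2)` over co-called sites — stated explicitly
so trees are reproducible. Neighbor joining is the standard Saitou–Nei
agglomeration with Q-matrix minimisation; among equal-Q pairs the
lexicographically smallest label pair is joined, making output
deterministic under taxon-order permutations (the trees are isomorphic
with identical patristic metrics). Branch lengths are clamped at zero.
By default, diversity runs on the MAF-5% filtered site set.

## Synthetic panel

The generator emits coverage summaries and tracks directly under the
stated statistical model rather than simulating reads: per bin, an
*alignable fraction* f is 1 for sequence the line carries,
`epsilon_conserved` (default 0.01) for alien sequence it does not, and
intermediate values for the diverged assembly background of the
haplotype contig (0.9 for carriers, 0.75 for non-carriers). Mapped reads
per bin are Poisson with mean `depth × f × bin / read_length`; covered
bases follow `f · bin · (1 − e^(−d_local))` with the realised local
depth; mean MQ is drawn near 35 for true homology and near 10 for
conserved pickup, aggregated per sequence weighted by reads. Defaults:
30 lines at uniform 5–20× (per-line depths are not individually
specified by the study design, so they are sampled uniformly), 1 Mb
bins, six chromosomes at one-tenth wheat scale, a 3.3 Mb segment on 2A
(~4% of the chromosome), a 16 Mb arm translocation on 1B (23.5% of the
chromosome, matching the observed ~23% breadth drop), a 53.3 Mb alien
chromosome of which 30% is the translocated arm, and a 2.8 Mb haplotype
contig with three planted 100 kb carrier-specific regions on a 50 kb bin
grid.

Genotypes: per-site true alternate-allele frequency uniform on (0, 0.5];
inbred lines are homozygous with that probability; heterozygous errors
at rate 0.01; missingness `e^(−depth/2)` so low-depth lines lose more
calls. These two model choices are generator conventions (exposed in
the config), not estimates from data.

What the generator does **not** emulate: repeat content, GC bias,
paired-end structure, mapping ambiguity beyond a scalar MQ, population
structure or linkage between sites. Passing tests therefore demonstrate
that the decision rules recover truth when the coverage signatures have
the modelled statistical structure — not that the thresholds are optimal
on any particular real panel.

## Problem sizes and numerics

The default panel (30 lines × 3 references × ~7 sequences at 1 Mb bins,
5,000 variant sites) was chosen so the complete detector sweep runs in
under a second and the whole suite in seconds, while keeping ≥ 50 bins
per sequence so breadth and ratio statistics are in their asymptotic
regime. Coverage percentages are stored to 4 decimals and validated
against covered-base counts to 0.01. The region-ratio pseudocount (0.1)
guards division by an all-zero non-carrier bin; scaling all depths by
*c* with the pseudocount scaled by *c* leaves regions unchanged.
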