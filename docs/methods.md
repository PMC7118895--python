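# Methods

This note documents the models, conventions and numerical choices behind
`triobin`, what the synthetic data generator does and does not emulate, and
the limitations a user should know before trusting results on real data.

## Marker construction and read binning

Canonical k-mers are the lexicographic minimum of a k-mer and its reverse
complement, packed into 64-bit base-4 codes (so string order equals numeric
order and k ≤ 31). Windows containing any non-ACGT base are skipped
entirely, with no substitution — the behaviour of standard counters. k is
restricted to [11, 31]; odd k is recommended because even k admits
palindromic k-mers that equal their own reverse complement (allowed, but a
warning is issued). k defaults to 21; every serialized marker table records
its k in a header line so mixed-k comparisons fail fast.

Markers are the set difference of the two parental count tables filtered by
an own-parent count window: maternal count ≥ 4, paternal count ≥ 6, and an
*exclusive* ceiling of 100 (count < 100). The asymmetric minima reflect the
different parental coverages the thresholds were designed for; the ceiling
removes repeat-derived k-mers. Marker sets are disjoint by construction.

Read classification counts marker *windows*, not distinct markers: a marker
occurring twice in a read contributes two hits. The read is assigned to the
haplotype with the strictly greater hit count; ties and zero-hit reads stay
unclassified (only zero-marker reads are truly uninformative; strict ties
are vanishingly rare at interspecies divergence). An optional `normalize`
flag divides hit counts by marker-set size before comparison — the
convention of earlier trio-binning classifiers — and is off by default. No
minimum-hit threshold beyond ≥ 1 is applied.

## Hi-C pair assignment

Reads are trimmed at the first occurrence of the DpnII ligation junction
`GATCGATC`; the retained prefix ends with the junction's first `GATC`
(the genuine restriction site of the first ligated fragment) — the standard
Hi-C convention, documented here because only "trimming to the junction" is
conventionally specified. Pair scores sum the `AS` tag over the two mates'
*primary* alignments; secondary/supplementary records are ignored and an
unmapped mate contributes 0 rather than a penalty. The pair goes to the
haplotype with the larger score; with the default margin of 0, "equally
well" is exact score equality and such pairs are usable for both
assemblies. Exact duplicate records are tolerated idempotently; conflicting
duplicate primaries are an input error.

## Parentage exclusion

A site enters the test when it is biallelic, all three genotypes are
present, and at least two distinct alleles appear among the trio
("polymorphic in the trio", matching discovery-mode calling restricted to
the trio). Sites with the interspecies-cross signature — sire homozygous
for the *reference* allele specifically, dam homozygous for the alternate,
child heterozygous — are tallied separately and excluded from the
denominator, because every true cattle × yak mating produces them and they
carry no parentage information. A laxer variant (any opposite-homozygous
parents with a het child) is available behind `strict=False` for
sensitivity analysis. The exclusion rate is Mendelian failures over
analyzed sites; the report does not distinguish sire- from dam-side
failures of the tested pairing.

## Window SNP rates and panel comparison

Depth bounds are per-sample symmetric nearest-rank percentiles: the low
bound is the ⌈0.025·N⌉-th smallest position depth and the high bound the
⌈0.025·N⌉-th *largest*; retention is inclusive of both bounds. (This
symmetric form is what reproduces, e.g., bounds (25, 976) on depths
1..1000.)

Genotypes are called from the pileup base column by non-reference allele
fraction f: f ≥ 0.8 homozygous-alt, 0.2 ≤ f < 0.8 heterozygous, f < 0.2
reference. These thresholds are this package's choice — the calling rule
used historically with such pileups is unpublished — and are configurable.
At depths ≤ 3 positions are typically removed by the lower percentile
bound; behaviour at such depths is NOCALL rather than a forced call.

Rates use the printed formula (hom + 0.5·het) / genotyped bases over fixed
50-kb tiles anchored at coordinate 0; the denominator is genotyped bases,
not window width, so NOCALL positions do not dilute the rate. Windows with
nothing genotyped are undefined and flagged, and drop out of downstream
denominators. Panel means drop individuals undefined in that window; a
window is *decided* when both panel means are defined and differ, which
makes panel swapping exactly antisymmetric (p ↔ 1 − p).

Discordance uses the strict all-individuals rule: a window is discordant on
an assembly when every individual of the assembly's own species has a
strictly higher rate there than every individual of the other species.
Runs of discordant windows merge into regions; a region reciprocally
discordant on the other assembly is a SWITCH_CANDIDATE (the two assemblies
traded haplotypes), otherwise an INTROGRESSION_CANDIDATE (one haplotype
genuinely resembles the other species there). Homologous windows across
the two assemblies are matched by identical coordinates — exact for the
collinear simulated assemblies, an approximation for real ones.

## Gap closure and telomeres

A gap is a maximal N-run of length ≥ 10 (the reference's own gap inventory
carries no run-length definition; 10 avoids counting isolated ambiguous
bases). 500 bp flanks are taken immediately before and after the run;
flanks truncated by a sequence end, or overlapping an adjacent gap, are
flagged. Closure requires both flanks' primary alignments on one target
scaffold, inner-end separation ≤ 100 kb, no target N-run overlapping the
spanned interval, and concordant orientation (same strand, ordered
accordingly); discordant orientation is logged and yields OPEN. Flanks on
different scaffolds give TRANS_SCAFFOLD; a missing primary alignment gives
UNPLACED. Separation is measured between the inner ends of the two flank
alignments and clipped at 0 for overlapping alignments.

Repeat intersection counts BED elements (by name, e.g. L1, BovB) sharing at
least one base with each flank or intervening span; half-open intervals
mean an exactly abutting repeat does not count.

Telomeres: a sequence end is telomeric when `TTAGGG` occurs ≥ 5 times in
the final kilobase. Occurrences are counted with overlap allowed — for the
non-self-overlapping TTAGGG this equals non-overlapping counting, noted for
general motifs. The null tail probability of ≥ c hits in an i.i.d.
uniform-base window uses a Poisson approximation with
λ = (window − m + 1)·4⁻ᵐ; for c = 5, m = 6, 1 kb this gives ≈ 5.8×10⁻⁶,
which the test suite cross-checks against a 3×10⁷-replicate Monte Carlo
over literally simulated windows (agreement within 20%; at that replicate
count the estimator's own sampling error is ≈ 8%). A much smaller bound
(10⁻⁷) is sometimes quoted for this threshold; a uniform-base null does not
reproduce it, and this package reports the computed value while using the
≥ 5 count threshold operationally.

## The synthetic trio generator

The generator's defaults are the study conditions: 1.2% SNP divergence
between the parental lineages (the heterozygosity regime of a yak × cattle
F1) plus ~0.1% short (1–10 bp) indel events (`indel_rate` is the fraction
of divergence events that are indels, 0.077 by default); 2×150 bp parental
short reads at 30×; log-normal F1 long reads (σ = 0.5, truncated at 1 kb)
with 15 kb mean at 20× diploid coverage and 10% per-base error with
mismatch:insertion:deletion weights 1:1:1 (long-read platforms are not
otherwise characterized here); Hi-C pairs with a discretized Pareto (α = 1,
x_m = 1 kb) separation capped at the chromosome, a 20% ligation-chimera
rate with the embedded `GATCGATC` junction, and simulated alignment records
whose `AS` follows the documented contract score = matches − 4·mismatches
(clipped at 0, edits taken from truth) — a contract mimicking a standard
aligner's scale, not a claim about any aligner; 2% per-genotype error
applied as a single random allele flip (the allele-dropout/undersampled-het
regime of ~14× genotyping panels). Parents are diploid with a configurable
within-parent heterozygosity (default 0.1%) realized as a second haplotype
sampled per fragment.

Every emitted read, pair, site and gap has exactly one truth record; truth
coordinates are 0-based half-open on the emitting haplotype, converted to
1-based only at VCF/pileup/SAM boundaries. All randomness derives from
`default_rng([seed, stage_tag])`, so identical (config, seed) reproduces
byte-identical outputs and stages are independently stable.

What the generator does **not** model: instrument-specific error profiles,
GC and coverage bias, the genomic spacing of DpnII sites, structural
variation beyond small indels, linkage structure in the genotype panel, or
mapping artefacts (simulated alignments are placed at their true positions).
Passing tests therefore demonstrate the correctness of the classification
logic under the stated statistical structure — not performance on real
libraries, where alignment error and bias add failure modes upstream of
these stages.

## Problem sizes used in the test and acceptance runs

Checks run at desk scale by design: parental genomes of 1 Mb total (two
500-kb chromosomes) for the binning checks, 500-kb single-chromosome panels
(10 windows) for the phasing fixtures, 10⁵ sites × 5 seeds for the
exclusion separation, and 3×10⁷ Monte Carlo windows for the telomere null.
Full-scale assembly metrics (contig N50s, genome-wide window fractions,
hundreds of closed gaps, ~350 M markers per parent) require the real reads
and external assemblers and are outside what this package computes.

## Known limitations

- Marker counting is in-memory; it is sized for desk-scale genomes, not
  for 10⁹-k-mer real datasets (no disk-backed or probabilistic counting).
- Whether historical pipelines normalized read hits by marker-set size, or
  summed Hi-C `AS` over non-primary alignments, is not recorded anywhere;
  both choices here default to the simplest reading (raw counts; primaries
  only) and the alternatives are exposed as options.
- The gap-closure "no intersecting gaps" condition is interpreted as no
  target N-run strictly between the two flank alignments.
- The phasing window match across assemblies assumes collinearity, which
  holds in simulation only.
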