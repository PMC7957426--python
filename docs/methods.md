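# Methods

This note documents the models, parameter choices and numerical decisions
behind `bsribo`, and what the synthetic validation does and does not show
about real data.

## Bisulfite simulation and calling

**Generative model.** Each transcript is sampled with fixed-length sense-strand
fragments (RNA bisulfite chemistry is strand-preserving); the number of reads
per transcript is Poisson with mean `bs_depth · length / read_len`, so
`bs_depth` is mean per-base coverage — the natural dial, since the calling
rule is a coverage threshold. Per molecule, each planted site is methylated
with probability equal to its stoichiometry (0 at NSUN-dependent sites in the
*noNSUN* genotype); every unmethylated cytosine converts C→T with probability
`deamination_rate` (default 0.99, a realistic bisulfite efficiency);
methylated cytosines are fully protected (no over-conversion of m⁵C is
modelled). Uniform substitution errors (default 2×10⁻³/base) are applied after
conversion; indels are not modelled, which keeps the desk-scale aligner exact.

**Alignment.** The unique aligner is an exact seed-and-verify scan over the
transcriptome. Matching in bisulfite mode is asymmetric: read T matches
reference C (conversion) but read C does not match reference T. Seeding uses
the pigeonhole principle on C→T-collapsed sequence — collapsed mismatches are
a subset of asymmetric mismatches, so every location within the mismatch
budget (default 2) is found and tie detection is exact: reads with two or
more equally good best locations are discarded, never tie-broken. Reference
preparation appends the 3′ CCA to tRNAs when missing and merges
bisulfite-identical sequences (identical after C→T collapse), keeping C at
every polymorphic position so methylation on either allele remains
observable.

**Pileup and calling.** At reference cytosines a read C increments
`nonconverted`, T increments `converted`; any other base is a sequencing
error and is excluded from coverage. Coordinates are 0-based half-open
internally and 1-based in exported TSVs. The caller requires coverage ≥ 11
("higher than 10") in every required replicate of both genotypes, then labels
positions from ratios pooled across replicates (per-replicate ratios are kept
in the output for audit; pooling stabilises low-coverage sites). The
knockout ceiling reuses the 0.1 threshold symmetrically. A fifth label,
`ko_exclusive_artifact`, covers positions non-converted only in the knockout;
it is the mirror image of the NSUN-dependent class and is what the threshold
sweep counts on the knockout side. No multiple-testing correction is applied:
the rule is thresholding, not testing. The deamination-rate estimate,
converted/(converted+non-converted), is computed on rRNA with planted
(known) sites excluded.

**Planted truth.** The default plan emulates an NSUN methylome: 100
NSUN-dependent sites — tRNA variable-loop positions 48–50 at stoichiometry
0.7–1.0 plus exactly one wobble-34 site on the Leu-CAA tRNA, rRNA sites at
0.8–1.0 (nuclear and mitochondrial), and rarer mRNA sites at 0.5–0.8 — plus
30 NSUN-independent artifact sites (stoichiometry 0.2–0.6, identical in both
genotypes). mRNA sites avoid the outer `read_len` nucleotides of long
transcripts, where fragment coverage tapers.

## Ribosome-profiling simulation

A footprint's P-site is drawn over (gene, sense codon) with weight

    expression(g) · noise(g, sample) · scale(g) · dwell(codon)

where `dwell` is the per-codon relative dwell for the sample's (genotype,
condition). Within a gene, footprint density is proportional to dwell — slow
codons accumulate ribosomes locally. Across genes, `scale` implements
stall-coupled output loss: a gene's total footprint load scales as
`2^(−g·log2(mean dwell)²)` relative to its RNA abundance (curvature
`te_feedback`, default 10). The quadratic-in-log form mimics ribosome
queueing: a gene carrying only background levels of a slowed codon (mean
dwell ≈ 1.02) is essentially untouched (−0.01 log2), while a UUG-enriched
gene (mean dwell ≈ 1.14) loses ~0.35 log2 of output. A linear exponent
cannot do both at once: it either cancels exactly against the within-gene
dwell sum (no TE effect) or depresses every gene through its background UUG
content (no clean random-set null). With uniform dwell the model reduces to
load ∝ expression × CDS length.

The 5′ end sits 12 nt upstream of the P-site first nucleotide; length is
drawn from the footprint length distribution (26–32 nt, mode 28); with
probability `frame_noise` (default 0.05) the 5′ end is re-drawn uniformly
over frame offsets {−1, 0, +1}, so the expected modal-frame fraction is
(1−f)+f/3. RNA-seq abundance is dwell-independent, with the same per-gene
log-normal overdispersion (σ = 0.1 log2, a typical replicate CV) drawn from
an independent stream; it is emitted as true counts by default (fast path) or
as uniform fragments (full path). Expression levels are log2-normal
(σ = 0.8) from the master seed; per-sample RNG streams are keyed by
(seed, stage, genotype, condition, replicate), so adding a sample never
perturbs another.

## Profiling analysis

Read lengths are retained when the modal fraction of (5′ end − CDS start)
mod 3 over CDS-overlapping reads reaches `min_frame_fraction` (default 0.5 —
permissive on clean data, rejects frame-uniform lengths). A single +12 nt
P-site offset is used for all retained lengths; off-frame shifted reads are
dropped and counted, and counts on the first 10 codons are removed. The
bookkeeping is exact: CDS-assigned reads = off-frame dropped + first-10
removed + table total, asserted on every run.

Occupancy normalisation uses the three codons downstream of the A-site
(nucleotide offsets +6, +9, +12 from the P-site first nucleotide; the A-site
is P+3 nt), with the background aggregated as the mean of the three offset
tallies so the uniform case normalises to 1. Ribosome positions whose
background window would cross the stop codon are skipped entirely.
Neutrality of this estimator is asymptotic: on a small transcriptome each
codon's P-site and background position sets differ by a few CDS-boundary
slots, a finite-reference composition bias (~±8% at 40 genes, independent of
depth; ~±4% at 120 genes). The neutrality experiment therefore uses 120
genes with 200–300-codon CDSs at 500,000 footprints/sample, where counting
error (~1.5%/codon) and boundary bias together stay well inside ±10%.

Fold changes between genotypes are computed per codon after median-centring
each replicate's log2 occupancies: occupancy is compositional (a strong
stall at one codon deflates every other codon's share by 1–3%), and without
centring a replicate t-test flags that global shift at dozens of codons. The
fold change is the ratio of geometric means of centred occupancies, tested
with Welch's t-test (the replicate-variance-robust choice) at α = 0.05; an
uncentred arithmetic variant is available (`center=False`).

TE is footprint CPM / mRNA CPM over genes passing an mRNA floor of 10 counts
(CPM rather than size-factor normalisation keeps TE self-contained; the
floor avoids ratio blow-up). Because CPM is itself compositional, log2 TE is
median-centred per sample group before between-genotype Welch comparisons —
the median-of-ratios idea — so a genuine loss in one gene set does not
masquerade as a gain everywhere else. Codon-enrichment sets use the
inclusive ≥ 3-fold rule on sense-codon proportions, with the boundary
evaluated by integer cross-multiplication so an exactly 3-fold gene is never
lost to float division; amino-acid-level sets pool synonymous codons. Random
control sets are seeded and size-matched. The polysome fraction is a
trapezoid area ratio with the boundary interpolated onto the trace.

## Study conditions and power

The canonical validation design (module `bsribo.study`): 60 mRNAs
(120–180 codons, 60 nt UTRs), 20 tRNAs, 2 rRNAs; 10 mRNAs carry UUG at 9%
per-gene frequency — enough genes that the transcriptome proportion stays
low and the ≥3-fold rule yields 6–8 enriched genes, and enough members that
the Welch TE test has large expected margin (effect ≈ −0.45 log2 against a
standard error ≈ 0.06). Bisulfite: ~50× coverage, 3+3 replicates. Profiling:
200,000 footprints/sample, 3 replicates per genotype at 27 °C, with a 2.5×
UUG dwell multiplier planted in *noNSUN*; measured fold change recovers
2.35–2.47 across seeds (the small deficit is real: UUG-dense genes place UUG
in their own background windows, and stall-coupled load loss shifts gene
weights). The null calibration of the set-vs-random TE test uses 20 random
seeds against the binomial 99.9% bound.

## What the synthetic validation does not show

The generator draws i.i.d. random sequences; real transcriptomes have codon
usage bias, secondary structure (which biases both bisulfite accessibility
and footprint recovery), paralogous sequence families far beyond the
C→T-twin merging exercised here, and position-dependent coverage from
library chemistry. The aligner is exact and ungapped on a tiny reference;
genome-scale gapped alignment, PCR duplicates, and quality-aware calling are
out of scope. Dwell modelling is single-codon: no codon-pair or dipeptide
effects, no mitochondrial codon-table differences, and no hm⁵C/f⁵C
chemistry. Passing tests therefore demonstrate the correctness of the
computational contracts and the statistical calibration of the rules on data
matching the stated generative assumptions — not performance on real
libraries.
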