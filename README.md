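# bsribo

Knockout-controlled RNA bisulfite m⁵C site calling and ribosome-profiling
codon-occupancy / translation-efficiency analysis, exercised end-to-end on
synthetic two-genotype data with planted ground truth.

## The problem

RNA 5-methylcytosine (m⁵C) resists bisulfite-driven C→U deamination, so a
cytosine that stays a **C** in sequencing after bisulfite treatment is a
candidate methylation site — but incomplete conversion produces the same
signal. The decisive control is genetic: in a strain with all NSUN
methyltransferases inactivated (*noNSUN*), genuine NSUN-dependent sites
disappear while conversion artifacts persist. The calling rule is

* per-cytosine **non-conversion ratio** = C-calls / (C-calls + T-calls),
* coverage > 10 in every replicate of both genotypes,
* pooled wild-type ratio > 0.1 **and** pooled knockout ratio ≤ 0.1
  ⇒ NSUN-dependent m⁵C; high in both genotypes ⇒ artifact.

Loss of the wobble modification m⁵C34 on tRNA-Leu(CAA) slows decoding of UUG
codons. Ribosome profiling quantifies this: footprint 5′ ends are shifted
+12 nt to the P-site, reads on the first 10 codons are discarded, and bulk
**codon occupancy** for codon *c* is

    occ(c) = P-site counts(c) / mean(counts of c at the +1, +2, +3 codons
                                     relative to the A-site)

with the A-site one codon downstream of the P-site. Stalling shows up as
elevated occupancy in *noNSUN* versus wild type (fold change per codon, Welch
t-test across replicates). Gene-level consequences are measured as
**translation efficiency** TE = footprint CPM / mRNA CPM and compared between
genotypes for UUG-enriched genes (a gene is enriched when its UUG proportion
is ≥ 3-fold the transcriptome proportion), with a seeded random gene set as
control. A polysome trace's translational activity is summarised as the area
fraction beyond the monosome/polysome boundary.

Every stage is validated against a synthetic generator that plants the truth:
methylation sites with known stoichiometry and NSUN dependence, conversion
artifacts present in both genotypes, and footprints whose per-codon dwell is
elevated at chosen codons in chosen (genotype, condition) pairs.

## Layout

* `src/bsribo/` — the library: `sim/` (reference, planted truth, bisulfite
  and footprint read simulation), `bsalign` (CCA appending,
  bisulfite-identical merging, unique asymmetric C/T alignment, cytosine
  pileup), `methcall` (deamination rate, site calling, threshold sweep,
  isoacceptor summary), `riboprof` (periodicity gating, P-site assignment,
  occupancy, fold changes, TE, gene sets, profiles, polysome fraction),
  `study` (the canonical study conditions), `pipeline` + `cli`
  (orchestration, manifest, report).
* `analysis/` — numbered drivers that run each analysis and write tables
  under `results/`.
* `configs/demo.yaml` — a small end-to-end pipeline configuration for
  `bsribo all`.

## Worked example

```bash
python analysis/01_call_m5c_sites.py
python analysis/03_translation_efficiency.py
```

prints (seed 1):

```
m5C calling on planted truth
  planted NSUN-dependent sites : 100
  recovered (recall)           : 100 (100.0%)
  artifacts mislabelled        : 0 of 30
  false NSUN-dependent calls   : 0
  deamination estimates        : WT_rep0=0.9888, WT_rep1=0.9898, WT_rep2=0.9896

translation efficiency, noNSUN-27C vs WT-27C
  UUG-enriched genes (>=3-fold rule)  : 6
  enriched set: dlog2TE -0.703  p 2.07e-04
  random set  : dlog2TE -0.011  p 0.897
  null calibration (20 seeds)         : 5% rejections at alpha=0.05
```

All 100 planted NSUN-dependent sites are recovered with no artifact
mislabelled; the simulated 99% bisulfite efficiency is re-estimated from rRNA
to within 0.2%. Under the planted 2.5× UUG stall the UUG-enriched gene set
loses ~0.7 log2 units of translation efficiency in the knockout (Welch
p ≈ 2×10⁻⁴) while a size-matched random set is unchanged.
`analysis/02_codon_occupancy.py` shows the occupancy side: UUG is the top
fold-change codon (FC 2.36, p ≈ 5×10⁻⁶) with neutral codons at the nominal
false-positive rate, and under uniform dwell every normalized occupancy stays
within ±9% of 1.

The same analyses run from one config through the CLI:

```bash
bsribo all --config configs/demo.yaml --outdir scratch/demo
cat scratch/demo/report/summary.json
```

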