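# Demo pipeline configuration: two genotypes, two bisulfite and two profiling
# replicates each, planted m5C truth and a 2.5x UUG stall in the knockout
# under heat. Completes in a couple of minutes on one CPU.
seed: 42
simulation:
  n_mrna: 20
  n_codon_biased: 3
  biased_codon_freq: 0.12
  cds_len_range: [100, 150]
  n_trna: 10
  n_rrna: 2
  rrna_len: 400
  bs_depth: 25
  ribo_depth: 60000
  rna_depth: 120000
  dwell_multipliers:
    - {genotype: noNSUN, condition: "27C", codon: TTG, multiplier: 2.5}
bs_replicates: 2
ribo_replicates: 2
conditions: ["27C"]
calling:
  n_replicates_required: 2
site_specs:
  - {ref_class: tRNA, n_sites: 12, stoich_range: [0.7, 1.0]}
  - {ref_class: rRNA, n_sites: 4, stoich_range: [0.8, 1.0]}
  - {ref_class: mRNA, n_sites: 10, stoich_range: [0.5, 0.8]}
  - {ref_class: mRNA, n_sites: 6, stoich_range: [0.2, 0.6], nsun_dependent: false}
sweep:
  thresholds: [0.25, 0.30, 0.35, 0.40]
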