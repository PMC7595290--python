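# Bundled demo: small three-population cohort with clinal admixture between
# pops 0 and 1, one strongly divergent haploblock, skewed-depth artifact
# sites, and a presence/absence sex marker absent in pop 2 males.
out_dir: demo_out
seed: 7
simulate:
  pop_sizes: [16, 16, 16]
  fst: [0.08, 0.08, 0.12]
  n_loci: 900
  chrom_lengths: [6000000, 4000000]
  mean_depth: 35
  missing_rate: 0.03
  admixture_cline:
    pop_a: 0
    pop_b: 1
    n_weights: 32
  planted:
    - kind: divergent_haploblock
      chrom: chr1
      start: 2000000
      end: 2200000
      params:
        n_loci: 10
        pop_freqs: [0.95, 0.9, 0.05]
    - kind: artifact_site
      chrom: chr2
      start: 1500000
      end: 1500000
      params:
        n_loci: 1
    - kind: artifact_site
      chrom: chr2
      start: 2500000
      end: 2500000
      params:
        n_loci: 1
    - kind: sex_marker
      params:
        carrier_sex: M
        negative_pop: 2
stages: [simulate, filter, structure, scan, assoc, ld, diversity]
n_pc: 4
k_max: 6
n_perm: 150
assoc_trait: sdY_present
assoc_n_covar_pc: 2
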