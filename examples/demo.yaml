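# a small demonstration cohort: 80 twin pairs, 20 genes, 4 with a true
# age effect of +/-0.05 sd/yr
n_mz_pairs: 40
n_dz_pairs: 40
n_genes: 20
effect_profiles:
  - {beta_age: 0.05}
  - {beta_age: 0.05}
  - {beta_age: -0.05}
  - {beta_age: -0.05}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
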