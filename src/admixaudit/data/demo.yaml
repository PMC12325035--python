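# End-to-end synthetic demo: 26 admixed populations (sizes 10..80, 8:1),
# European-ascertained array subset, full audit pipeline.  Sized to finish
# in a few minutes on one CPU; raise m / bootstrap_B for larger studies.
seed: 1
stages: [simulate, qc, ascertain, validate, structure]
simulate:
  m: 8000
  n_populations: 26
  miss_rate: 0.002
  err_rate: 0.0059
  r_err: 0.4
  array:
    discovery_ancestry: EUR
    discovery_n: 120
    maf_cutoff: 0.05
qc:
  min_call_rate: 0.95
  min_maf: 0.01
  min_hwe_p: 1.0e-6
  max_pihat: 0.185
  kinship_max_variants: 8000
ascertain:
  bins: [0.0, 0.005, 0.01, 0.05, 0.10, 0.5]
validate:
  r_exp: 2.1
  r_err: 0.4
  mode: ratio-linear
structure:
  k: 4
  weight_mode: inverse-group-size
  bootstrap_B: 30
  grs_n_auto: 50
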