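simulate:
  n_subpop1: 60
  n_subpop2: 25
  n_admixed: 10
  loci_per_chromosome: [6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6]
  mean_spacing_cm: [8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0]
  divergence: 0.4
structure: {k_max: 6}
resample: {step: 24, reps: 10}
ld: {n_shuffles: 1000}
diversity: {n_bootstrap: 200}
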