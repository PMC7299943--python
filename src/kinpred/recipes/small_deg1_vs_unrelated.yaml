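name: small_deg1_vs_unrelated
simulation:
  n_families: 600
  sibship_size: 2
  n_generations: 2
  n_snps: 800
  maf_range: [0.1, 0.5]
  h2: 0.5
  f2: 0.2
  seed: 11
design:
  scale: small
  degree: 1
  n_discovery: 400
  n_target: 100
  seed: 7
  compare_unrelated: true
analysis: [prs]
evaluation: [accuracy, me, theory]
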