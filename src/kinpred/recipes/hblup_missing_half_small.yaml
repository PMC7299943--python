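# Scaled copy of hblup_missing_half (one-tenth size) for smoke testing.
name: hblup_missing_half_small
simulation:
  n_families: 100
  sibship_size: 4
  n_generations: 2
  n_snps: 600
  maf_range: [0.1, 0.5]
  h2: 0.5
  f2: 0.0
  seed: 21
design:
  scale: small
  degree: "1"
  n_discovery: 500
  n_target: 100
  seed: 9
analysis: [prs, gblup, hblup]
evaluation: [accuracy, me]
n_ungenotyped: 300
ungenotyped_seed: 13
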