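# Ungenotyped-relative experiment at full printed size: 5000 discovery
# (2000 genotyped + 3000 ungenotyped phenotyped relatives) and 1000
# genotyped targets.  Several minutes of dense REML; a scaled copy
# (hblup_missing_half_small) exists for quick smoke runs.
name: hblup_missing_half
simulation:
  n_families: 1000
  sibship_size: 4
  n_generations: 2
  n_snps: 2000
  maf_range: [0.1, 0.5]
  h2: 0.5
  f2: 0.0
  seed: 21
design:
  scale: small
  degree: "1"
  n_discovery: 5000
  n_target: 1000
  seed: 9
analysis: [prs, gblup, hblup]
evaluation: [accuracy, me]
n_ungenotyped: 3000
ungenotyped_seed: 13
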