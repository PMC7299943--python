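# Methods

## Scope and model

`kinpred` studies how relatives in the reference (discovery) sample change
the accuracy of polygenic prediction.  Everything runs on simulated
family-structured data, so each claim is checkable against known truth.

The phenotype model is

    y_j = g_j + f_j + e_j,

with `g` an additive polygenic value, `f` an environmental effect shared by
all members of a family, and `e` an independent residual.  Two heritabilities
follow:

    h2_narrow = sigma_g^2 / (sigma_g^2 + sigma_e^2)
    h2_family = (sigma_g^2 + sigma_f^2) / (sigma_g^2 + sigma_f^2 + sigma_e^2)

Narrow-sense heritability is what a sample of unrelated individuals
identifies; family-based heritability also absorbs the shared-family
variance and is the relevant quantity when close relatives carry the
prediction signal.

The theoretical accuracy of a polygenic predictor trained on N phenotyped
reference individuals is

    r = h^2 / sqrt(h^2 + Me / N),

where Me, the effective number of chromosome segments, is estimated
empirically as the inverse of the variance of genomic relationships between
reference and target individuals, Me = 1 / var(G_ij).  Relatives of a
target inside the reference contribute large G_ij entries, inflate that
variance, shrink Me, and thus raise the expected accuracy.  The analytic
what-if operation appends the expected relationship of an added relative
(0.5, 0.25, 0.125 for first/second/third degree) to a baseline relationship
vector and recomputes Me.

## Simulator

* **Pedigrees.**  Nuclear families: a founder couple with `sibship_size`
  children; with three generations each child mates a new unrelated founder
  and has `sibship_size` children, which creates second-degree
  (grandparent, avuncular) and third-degree (first-cousin) pairs.  Spouses
  are always unrelated founders, so no inbreeding loops arise by default.
* **Genotypes.**  Gene dropping: founder alleles are Bernoulli(p) with p
  uniform on `maf_range` (default 0.1–0.5); every non-founder receives one
  allele drawn uniformly from each parent's pair, locus by locus.  Loci are
  independent — there is no LD — so for unrelated samples
  var(G_ij) = 1/M and Me ≈ M, which makes the Me machinery checkable
  against a closed form.  Real genomes have LD (Me is tens of thousands,
  not M), imputation error, and genotyping artefacts; none of those are
  emulated, so passing tests validate the estimators and the relative-
  driven mechanism, not biobank-scale point values.
* **Phenotypes.**  On a unit-variance scale: `g` is built from
  standardized causal dosages with N(0, h2/M_causal) effects and rescaled
  so its in-sample variance is exactly h2 (this removes Monte-Carlo drift
  from parameter-recovery tests); `f` is drawn once per `family_id` with
  variance f2; `e` carries the remainder 1 − h2 − f2.  Full sibs therefore
  correlate at 0.5·h2 + f2, which the suite verifies directly.  Binary
  traits threshold the liability at its empirical (1 − prevalence)
  quantile, so the realized case fraction matches the requested prevalence
  up to ties.
* **Seeding.**  One master seed; founder frequencies, gene dropping and
  phenotype draws use independent streams derived from it by fixed stream
  offsets.  Identical configurations are bit-identical.

Defaults (M = 5000 SNPs, maf 0.1–0.5, h2 = 0.5, f2 = 0, sibship 3) are the
conditions the end-to-end checks run under; experiment-specific sizes live
in recipes.

## Relationship matrices

* **G = WW′/M** with per-SNP standardized dosages
  (w − 2p)/sqrt(2p(1 − p)); missing dosages are imputed to 2p before
  standardizing.  A raw 0/1/2 mode exists behind `standardize=False` for
  fidelity experiments, but raw coding cannot reproduce conventional
  thresholds (unrelated < 0.05, sibs ≈ 0.5), so the standardized form is
  the default.  Per-SNP standardization was chosen over the VanRaden
  sum-2p(1−p) denominator; both satisfy every invariant used here.
* **A** by the tabular method: a_ii = 1 + a_sd/2,
  a_ij = (a_j,sire + a_j,dam)/2, founders at identity.  Verified against a
  brute-force gene-dropping IBD oracle on every bundled pedigree.
* **H** merges the two for partially genotyped samples:
  H22 = G, H12 = A12 A22⁻¹G,
  H11 = A11 + A12 A22⁻¹(G − A22)A22⁻¹A21.  A singular A22 aborts with
  guidance to blend G ← (1−t)G + tA22; blending is opt-in (`blend=`),
  never silent.
* **Kinship** between two individuals uses the robust within-sample
  estimator φ = (N_Aa,Aa − 2N_AA,aa)/(N_Aa(i) + N_Aa(j)) over SNPs
  non-missing in both (missing calls are excluded pairwise).  Degrees use
  the powers-of-two boundaries 0.3536 / 0.1768 / 0.0884 / 0.0442; each
  bin is upper-inclusive and the outermost boundary 0.0442 itself still
  counts as third degree, so a tie always resolves toward the closer
  relationship.

## Study designs

Large-scale designs prune to a mutually unrelated pool (pair-at-a-time
random removal of one member of any pair above the threshold — fidelity to
the described procedure rather than a maximum independent set), split
80/20, and substitute relatives while preserving role sizes.  Small-scale
designs build the undirected degree-d relative graph, take whole connected
components from the largest down (ties broken by smallest member id; a
truncated component keeps its highest-graph-degree members first), then
split.  The TA/TB split variants force every target to have — or to lack —
a degree-matched relative inside discovery.

Inside the recipe pipeline the unrelated pool is pruned on the pedigree A
matrix rather than on G: at desk-scale M the sampling noise of a single
G entry (sd ≈ 1/√M ≈ 0.02–0.04) swamps a 0.05 threshold that is sharp
only at biobank SNP counts.  `prune_unrelated` itself accepts either
source.

## Predictors

* **PRS**: the trait is OLS-residualized on covariates once; each SNP is
  regressed on the residual (intercept included, missing dosages
  mean-imputed); scores are dosage-weighted sums of effects passing a
  p-value threshold (default 1.0 — all SNPs; there is no LD, hence no
  clumping).  Binary traits are analysed by linear regression on 0/1.
* **GBLUP / ABLUP / HBLUP** are one operation with different kernels:
  ĝ_t = K_td(K_dd + λI)⁻¹(y_d − μ̂), λ = σe²/σg², μ̂ the GLS mean.
  GBLUP is algebraically identical to SNP-ridge with per-SNP prior
  variance σg²/M, and the suite asserts this to 1e-6 against an explicit
  M×M ridge solve.
* **REML.**  Single component: eigendecompose K once and run a bounded
  Brent search on h2 with the total variance profiled out — exact and
  stable at desk scale (convergence tolerance 1e-8 on h2; identity-like K
  is rejected as unidentifiable; eigenvalues below −1e-8 reject K as
  non-PSD).  Two components (g + f + e): direct maximization of the REML
  log-likelihood with its analytic gradient (L-BFGS-B, non-negativity via
  bounds at 1e-8, start at an equal split of the phenotypic variance, at
  most 200 iterations; non-convergence is flagged and the best point
  returned).  An EM or average-information iteration would reach the same
  stationary points; the gradient form is simpler and robust at these
  sizes.  Variance
  components are re-estimated on each discovery set by default; a
  truth-injection constructor (`VarianceComponents.from_heritability`)
  isolates prediction error from estimation error.  For HBLUP both modes
  exist: re-estimate under H (default in the pipeline) or reuse G-based
  estimates by passing them in.

## Evaluation

Accuracy is the Pearson correlation of scores with adjusted phenotypes in
targets.  Design comparisons report the mean per-trait fold change with a
95% t-interval on the ratio scale, a two-tailed paired t-test on the
differences, and (for transparency) a t-test of the raw folds against 1;
zero-variance differences are flagged degenerate rather than given p = 1.
Decile analysis ranks targets by score (ties broken by a seeded stable
shuffle) and reports prevalence and odds ratio against the population odds
in the cumulative strict upper tail above each decile boundary; a tail
with no controls yields an infinite OR flag, no cases yields OR 0.

Me uses the population variance (divisor = pair count) with the mean
subtracted; at the pair counts used the divisor choice moves Me by less
than 0.1%.  A zero variance (all relationships equal) is signalled as an
infinite Me rather than a number, and propagates to r = 0.

## Problem sizes in the checked experiments

The end-to-end suite runs: theory-versus-empirics at 2,500 discovery / 500
targets / M = 5,000 over 20 replicates; the sib-enriched versus unrelated
comparison at the same sizes (f2 = 0.2, one sib per target in discovery);
the ungenotyped-relative experiment at 800 genotyped discovery + 1,200
ungenotyped phenotyped relatives + 400 targets over 30 replicates; REML
recovery at n = 3,000 (single component) and 300 sibships of three over 20
replicates (two components).  These sizes give comfortable Monte-Carlo
margins for every asserted direction and tolerance while keeping the whole
suite in the tens of minutes on one core.

## Interchange formats

Genotypes travel as PLINK1 bed/bim/fam (variant-major; dosage counts the
A1/alternate allele; synthetic positions on chromosome 1).  Relationship
matrices persist as lower-triangle TSV at 12 significant digits plus an id
list; designs, GWAS results, scores, variance components and reports are
TSV with a provenance header (tool version, seed, input hashes).  Recipes
are YAML.  Everything round-trips exactly at the stated precision.

## Known limitations

No LD, no X chromosome, no genotyping error or imputation noise, no
dominance or GxE, no summary-statistic BLUP, no multi-trait models.
Binary traits are handled on the observed 0/1 scale throughout.  The
full-size ungenotyped-relative recipe (5,000 + 1,000) takes several
minutes of dense REML; its bundled one-tenth copy is what the smoke test
runs.
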