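# Methods

This note documents the statistical models implemented in `gatekit`, the
generative model behind its synthetic cohorts, the defaults and why they
were chosen, numerical details, and the limits of what the test suite
demonstrates.

## 1. The analysis model

### Scores from summary statistics

Inputs are marginal SNP-to-gene summary statistics (effect per effect-
allele dose on a standardized transcript or protein level) and individual
genotype dosages. Processing per gene:

1. **Allele harmonization.** Effect alleles are aligned to the genotype
   panel by allele-pair match; swapped pairs flip the effect sign;
   strand-ambiguous (A/T, C/G) SNPs are dropped and counted. This is
   standard score-building hygiene.
2. **Cis/trans classification.** A record is *trans* when the SNP is on a
   different chromosome than the gene or at least 5 Mb from its TSS
   (configurable `cis_window`; 5 Mb is the common eQTL-consortium
   convention), *cis* otherwise.
3. **Hotspot mask.** Trans records inside chromosome 6, 25-34 Mb (closed
   interval) are excluded from GATE aggregation and routed to a separate
   HLA-specific score set. The HLA region is a trans-hotspot with strong
   direct disease effects; leaving it in would let one locus confound
   every score it touches.
4. **Selection.** Trans records require `p < 5e-8` (genome-wide
   significance; the threshold is configurable because the appropriate
   value depends on the source study's multiple-testing burden). A cis
   score is only defined when at least one cis SNP reaches `p < 1e-6`.
5. **Clumping.** Surviving SNPs are grouped by single-linkage chaining:
   two SNPs share a clump iff they are connected by steps of at most
   200 kb. Chaining (rather than pairwise-complete grouping) gives a
   deterministic partition with no tie-breaking; on a line it reduces to a
   sorted gap rule, which the tests verify against brute-force graph
   connectivity.
6. **LD adjustment.** Within each clump, joint weights are obtained as
   `w = (R + ridge * I)^-1 b` from the marginal effects `b` and the
   reference-panel dosage correlation matrix `R`. With `ridge = 0` and
   invertible `R` this equals the multivariable regression coefficients in
   the reference population (exactly so for equal-variance genotypes; the
   synthetic panel shares MAF within a block, and for real data the
   per-SD convention applies). The ridge default 0.1 stabilizes
   near-collinear clumps while barely shrinking independent SNPs; a
   singular solve at `ridge = 0` raises an error advising a positive
   ridge. Whether a pruning rather than ridge strategy is preferable is
   an open choice; ridge was selected for determinism and smoothness.

A gene's GATE score is the dosage-weighted sum over all its trans clumps.
Genes with fewer than 5 clumps are excluded: aggregation is what converts
directionally consistent signal against random noise, and the filter keeps
a single strong trans-QTL from masquerading as convergence. Scores are
standardized on the full analysis cohort (cases plus controls) — per-SD
log odds ratios are the reporting convention and the full-sample SD is the
common choice; standardize-first (before covariate adjustment) is used.
Missing dosages are mean-imputed per SNP (unbiased under missing at
random). Adjusted weights are used as-is, with no per-locus
renormalization, preserving the joint-effect interpretation.

### Association and core-gene calls

Each standardized score is tested by maximum-likelihood logistic
regression with covariates (discovery set: sex, cohort, 10 genetic PCs;
replication set: sex, 20 PCs), reporting the Wald SE and p-value — Wald
rather than LRT so that the per-SD log OR and its SE are the headline
numbers. Perfect separation is flagged with an infinite-estimate sentinel;
degenerate covariates are dropped with a log entry.

Scores of analyzed genes are Pearson-correlated **over controls only**
(cases are enriched for high scores, which would inflate correlations),
then clustered by average-linkage hierarchical clustering on distance
`1 - |r|`, cutting the tree at `1 - 0.25`. The 0.25 threshold is a design
choice — "correlated" has no canonical cutoff — chosen to cleanly separate
shared-instrument blocks (|r| typically > 0.8) from sampling noise
(|r| ~ 1/sqrt(n)); it is exposed in the configuration. A gene is a
**putative core gene** when its score reaches `p < 1e-6` *and* its cluster
contains no other gene; significant members of multi-gene clusters are
reported as `cluster_member`, since shared trans-QTLs make the mediating
gene unidentifiable. No multiple-testing correction is applied beyond the
fixed 1e-6 threshold. Cluster listings include all members with the
minimum cluster p-value.

### Information for discrimination

For a rare disease with additive genetic effects on the logistic scale,
the total genetic information for discriminating cases from non-cases is
`log2(lambda_s)` bits for first-degree recurrence risk ratio `lambda_s`.
A standardized predictor with log OR `beta` contributes `beta^2/2` nats =
`beta^2/(2 ln 2)` bits. The GATE score is an imperfect predictor of the
trans-regulated expression component; the dilution factor
`r^2 / h2_trans` (the share of trans-heritable expression variance the
score captures) divides the observed information:

```
I = beta^2 / (2 log 2) / (r^2 / h2_trans)
```

`h2_trans` is an *input* (from external expression studies, or ground
truth in synthetic runs), not estimated from case-control data. `r^2` is
estimated as the squared Pearson correlation between score and measured
expression; estimates with `r^2 < 1e-3` are flagged unstable, and a
dilution exceeding 1 through sampling noise is clipped with a warning.
`r^2 > h2_trans` as a *stated input* is rejected as inconsistent.
Pathway-level information should be computed from a single combined score
(mean of standardized member scores) with a pathway-level dilution —
summing per-gene corrected estimates over correlated genes double-counts
shared trans effects, which is why a single gene's corrected estimate can
exceed a pathway total. Reported percentages are rounded to integers and
bits to two decimals.

### Mendelian randomization

Instruments are trans loci with exposure effect `b_j` (per-SD effect of
the lead SNP on expression, from the reference summary statistics) and
outcome effect `y_j` (per-SD log OR of that SNP on disease). The model is

```
y_j ~ Normal(theta * b_j + alpha_j, se_j^2)
alpha_j | tau, lambda_j ~ Normal(0, tau^2 * lambda_tilde_j^2)
```

with a regularized horseshoe: `lambda_j ~ half-Cauchy(1)`,
`tau ~ half-Cauchy(0.05)` (global scale on the log-OR scale, a prior
belief that typical pleiotropy is small relative to the mapped effects;
configurable), slab scale `c = 1`, and
`lambda_tilde_j^2 = c^2 lambda_j^2 / (c^2 + tau^2 lambda_j^2)`. The
conditionally Gaussian `alpha_j` are marginalized analytically, leaving a
likelihood over `(theta, log tau, log lambda_1..J)` with
`theta ~ Normal(0, 10^2)`. Sampling uses an affine-invariant ensemble
sampler (emcee) with 32 walkers, 250 burn-in and 750 retained steps
(24000 draws), vectorized across walkers; diagnostics (mean acceptance
fraction, integrated autocorrelation time, effective sample size) are
recorded and results with ESS < 100 or extreme acceptance are flagged
invalid. Exposure betas are plug-in by default (standard two-sample MR
practice); an option inflates the outcome variance by
`theta^2 * se_exposure^2`. The "support p-analog"
`2 min(P(theta>0), P(theta<0))` is a posterior tail probability, an analog
of — not a claim to be — a frequentist p-value. As the global scale tends
to zero the estimate converges to the inverse-variance-weighted slope
through the origin (verified against the closed form).

## 2. The synthetic architecture

The generator produces the structure the analysis assumes, so that every
stage is testable without any external download.

* **Genotypes.** Haplotypes are Gaussian copulas: within each LD block a
  latent AR(1) chain thresholded at the MAF quantile; blocks independent;
  dosage = sum of two haplotypes. The latent step correlation is
  *calibrated* (Owen's-T bivariate-normal identity plus root finding) so
  that the observable dosage-scale adjacent correlation equals
  `block_rho` — naive thresholding of a latent AR(1) would deflate the
  dosage correlation (e.g. 0.9 latent gives about 0.71 at MAF 0.5). MAF
  is drawn per block (uniform on `maf_range`, default [0.05, 0.5],
  mirroring a >= 5% MAF filter) and shared within the block so high
  correlation targets stay attainable. Coordinates are 1-based on
  chromosomes "1".."22"; an optional hotspot block sits at chromosome 6,
  25-34 Mb so the HLA mask is exercised verbatim.
* **Architecture.** Default: 5 core genes and 5 null genes, each with 8
  peripheral trans loci on disjoint LD blocks (always on a different
  chromosome than the gene) plus one cis SNP near the TSS; per-locus
  effect magnitudes uniform in [0.5, 1.5] x `trans_effect_sd` with random
  signs (bounded away from zero so configured loci are discoverable at a
  realistic reference size). An optional ISG-like cluster
  (`n_shared_genes`) shares a single locus set with per-gene beta jitter;
  only its first member carries a disease effect, making the cluster
  jointly associated but individually unresolvable — the situation the
  cluster rule exists for.
* **Hotspot.** One latent "antigen" axis (a weighted sum of the hotspot
  SNPs) carries both the direct disease effect (log OR 0.5 per SD) and
  positive trans loadings on every gene, calibrated on an internal cohort
  to contribute `hotspot_trans_share` (default 15%) of each gene's trans
  genetic variance. Sharing one axis is what makes HLA-specific scores
  disease-associated, as for a real immune trans-hotspot.
* **Expression.** `x = sqrt(h2_trans) T + sqrt(h2_cis) C + noise`, with T
  and C the standardized trans/cis genetic values and unit total variance;
  defaults `h2_trans = 0.4`, `h2_cis = 0.1`. Components are standardized
  within cohort, so realized variance fractions match the configuration up
  to sampling error (verified to +/- 0.05 at n = 10000).
* **Disease.** Logistic in the standardized *trans* genetic values of the
  core genes (per-SD log OR 0.3 each) plus the direct hotspot effect; the
  intercept is `logit(prevalence)` (default 0.1), i.e. prevalence is the
  disease probability at mean liability. A logistic rather than
  liability-threshold model matches the analysis model, so logistic
  recovery is exact in expectation; acting on the trans value (not total
  expression) makes the dilution correction exactly consistent: the
  marginal score coefficient is `beta_T * c` and `r^2/h2_trans = c^2`
  (c = score-trans-value correlation), so the corrected information
  recovers `beta_T^2/(2 ln 2)` regardless of score quality. Exact
  case/control counts are met by rejection sampling from a pool sized
  from the prevalence; an unreachable design raises an error with
  guidance. Sex, cohort and PCs are simulated with no disease effect by
  default; `covariate_confounding` adds a PC1 effect for robustness
  experiments.
* **Reference summary statistics.** A disjoint reference cohort provides
  marginal simple-regression effects, SEs and p-values of every SNP on
  every standardized expression column; monomorphic SNPs are skipped with
  a log entry; duplicated individuals are rejected. The reference cohort
  doubles as the LD panel, since the two roles use the same population.

What the generator does **not** emulate: real LD panels and their
long-range structure, imputation uncertainty, phasing, the X chromosome,
population stratification beyond cohort labels, assortative mating,
cell-type-specific expression, and winner's-curse effects in the source
QTL study. Passing tests therefore demonstrate the *internal* correctness
and calibration of the pipeline under its assumed architecture, not
robustness to these real-data complications.

## 3. Problem sizes and defaults in the test suite

The shared test study uses 1500 cases / 1500 controls with a 5000-person
reference cohort on a 300-SNP, 100-block panel; the end-to-end recovery
experiments use 5000/5000 with a 10000-person reference over 20
replicates, and the association calibration experiment uses 500 null
replicates at n = 2000. These sizes were chosen as the smallest at which
the targeted properties (oracle tolerances, type-I error in [0.03, 0.07],
sensitivity/precision >= 0.8) are comfortably identifiable.

## 4. Numerical choices and degenerate inputs

* Copula calibration solves on [0, 0.999999] with Brent's method; a target
  of 0 short-circuits to independence.
* `adjust_for_ld` validates symmetry, unit diagonal and dimension; solves
  with a positive-definite factorization; non-finite weights raise.
* Zero-variance scores are left unscaled (flagged), zero-variance
  correlation columns excluded, perfect separation sentineled as +/- inf
  with `se = inf`.
* Clump labels, cluster labels and run outputs are deterministic functions
  of (inputs, config, seed); all randomness flows through
  `numpy.random.Generator` seeded from a single `SeedSequence`, and the
  MR sampler state is seeded explicitly.
* p-values are clipped below by the smallest positive float to keep
  downstream logs finite.

## 5. Known limitations

* The ridge-joint weights are not a conditional fine-mapping; colocalized
  but distinct causal variants within a clump are treated as one locus.
* The per-SD instrument scaling in the MR stage uses the analysis cohort's
  dosage SD for both exposure and outcome effects; cohort mismatch in
  allele frequency would bias Wald ratios slightly.
* The information calculation assumes a rare disease and additive logistic
  effects; for common diseases `log2(lambda_s)` understates total
  information.
* Pathway-level aggregation is provided as a combined-score computation
  only; no attempt is made to partition information among correlated
  member genes.
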