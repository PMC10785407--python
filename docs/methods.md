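# Methods

`nihlkit` implements the statistical pipeline of a two-stage candidate-SNP
case-control study of occupational noise-induced hearing loss (NIHL): subject
classification from pure-tone audiometry, SNP quality control, association
under alternative genetic models, an unweighted genetic risk score (GRS) with
dose-response assessment, and classification-tree (CART) analysis of
gene-gene and gene-environment interactions. A synthetic-cohort generator
reproduces the statistical structure of such a study so that every stage is
testable without access to individual-level data.

## Phenotype definitions

Hearing is measured per ear at 500/1000/2000/3000/4000/6000 Hz (dB HL).
Two summary thresholds drive classification:

* **BHFTA** (binaural high-frequency threshold average): the mean of the six
  high-frequency thresholds (3000/4000/6000 Hz, both ears).
* **MTWV** (monaural weighted threshold value): per ear,
  `0.9 × mean(500, 1000, 2000 Hz) + 0.1 × threshold(4000 Hz)`.

A subject is a **case** when BHFTA ≥ 40 dB and MTWV ≥ 26 dB, a **control**
when BHFTA < 40 dB and MTWV < 26 dB, and **indeterminate** otherwise. MTWV
is a monaural criterion and the sidedness of the diagnostic rule is
genuinely open; we classify on the worse (larger) ear by default, the
conservative reading of a monaural criterion (`ear_rule` switches to the
better ear).

**Cumulative noise exposure.** Occupational dose combines the 8-hour
A-weighted sound pressure level (SPL, `L_Aeq,8h`) with exposure duration
under the equal-energy principle:

    CNE = SPL + 10·log10(years)   [dB(A)·years]

equivalently `10·log10(10^(SPL/10) · years)`. This is the standard
equal-energy form: one decade of exposure time adds 10 dB. (Formulations
that exponentiate the raw dB value, `10^SPL`, are dimensionally unusable at
occupational levels of 80–100 dB(A); the form above reproduces the expected
magnitudes, e.g. ≈96 dB(A)·years at 85 dB(A) and 12 years.)

## Genotype model and QC

Calls are `AA` (homozygous wild), `AB`, `BB` (homozygous variant), always
oriented to the panel's declared wild allele; VCF import flips homozygotes
when a panel declares REF to be the variant allele. Missing calls are
excluded per analysis (complete-case per SNP); subjects missing an
adjustment covariate are dropped only from adjusted fits.

QC excludes a SNP when its call rate is below 0.90 **or** its control-group
genotype counts depart from Hardy-Weinberg proportions at p < 0.01
(Pearson χ², 1 df, expectations from the estimated allele frequency).
OR-combination of the two filters is standard practice — an AND-combination
would retain SNPs that are unusable on either ground — and the report logs
both flags per SNP so either convention can be audited (`combine="and"` is
available).

## Association analysis

Each SNP is tested under five dichotomizations plus a dosage coding:
recessive (BB vs rest), dominant (AB+BB vs AA), super-dominant (AB vs
homozygotes), homozygote (BB vs AA, AB excluded), allele (per-allele
counting, two alleles per subject), and additive (0/1/2 dosage, regression
only). Exposure is fixed as the variant-containing grouping; the reciprocal
orientation is a label swap and the contingency table carries both.

* **Crude estimates**: cross-product OR `ad/bc` with Woolf (log-scale Wald)
  95% limits `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`; a zero cell triggers
  the Haldane-Anscombe correction (+0.5 to all cells, flagged).
* **Adjusted estimates**: Newton-Raphson (IRLS) logistic regression of
  status on the model coding plus age, years of exposure, smoking and
  drinking; convergence at log-likelihood change ≤ 1e−8, ≤ 100 iterations;
  Wald p-values throughout, for consistency with the Woolf limits. The
  unadjusted single-predictor fit reproduces the cross-product OR to 1e−6 —
  a closed-form identity the test suite uses as an oracle (statsmodels is
  the independent cross-check, never the implementation). Perfect
  separation (a coefficient diverging past |15| with non-shrinking steps)
  returns a flagged non-converged result rather than raising, since
  sparse-genotype models at n ≈ 166 hit it routinely.
* **Allele-model adjustment**: covariates cannot be attached to an
  allele-level table; the adjusted counterpart is subject-level additive
  dosage regression, flagged as such.

**Two-stage selection.** Stage 1 (screening cohort) keeps SNPs with
adjusted p < 0.10 under at least one model (significant: p < 0.05;
marginal: 0.05 ≤ p < 0.10); stage 2 keeps, of those, SNPs with adjusted
p < 0.05 under at least one model in the independent replication cohort.
No multiple-testing correction is applied by default — replication in an
independent sample set is the error-control device — but Bonferroni and
Benjamini-Hochberg switches exist.

## Genetic risk score

Each validated SNP's **risk allele** is the allele with replication-stage
allele-model crude OR > 1 (ties break toward the variant allele with a
warning). Per subject, each SNP contributes its risk-allele count (0/1/2)
and the GRS is the unweighted sum, range 0..2K for K SNPs. Subjects missing
any scored SNP are excluded (a prorated score is available, flagged).
Binned subjects are compared against the lowest-GRS bin by cross-product
OR; the default binning (≤5, 6, 7, 8, 9, ≥10) matches a six-SNP panel of
common variants, and collapses automatically to the observed range for
narrower panels. Dose-response uses the Cochran-Armitage trend test with
ordinal bin scores: `T = Σ s·(cases per bin)` compared with its exact
permutation mean and variance `R(N−R)/(N−1)·var(s)`, giving a 1-df χ².
The test suite verifies this against a brute-force permutation null.
A weighted GRS (per-allele lnOR weights) is deliberately out of scope.

## CART interaction analysis

From-scratch binary recursive partitioning over genotype (three level
bipartitions: {AA}, {BB}, {AB} vs the rest), boolean (one split) and
ordered numeric predictors (thresholds at midpoints of observed values, or
a fixed clinical cutpoint list such as age 45 / CNE 95).

* **Splitting**: information gain in bits (binary entropy impurity; Gini
  optional). Ties break by variable declaration order then partition
  enumeration order, so trees are bit-reproducible. An exhaustive
  brute-force oracle over all variables × partitions backs the search in
  tests.
* **Growth limits**: minimum 20 subjects per child node, maximum depth 6,
  purity and zero-gain stops — safety limits, not the model-selection
  device.
* **Pruning**: grow-then-prune cost-complexity pruning. The weakest-link α
  sequence is computed from the full tree; k-fold (default 10) stratified
  cross-validation scores each candidate subtree by held-out
  misclassification; the selected subtree is the smallest within one
  standard error of the CV minimum (1-SE rule, the classical CART choice).
  Plain CV-minimum selection is available (`one_se_rule=False`) but keeps
  chance structure on null data: finite noise clusters are shared between
  training and held-out folds, so overfit subtrees sit within noise of the
  root. A caveat worth knowing: with *exactly balanced* classes the root
  majority classifier is a coin toss in CV and even reference
  implementations fail to collapse null trees; with the study's unbalanced
  153:252 design, null collapse is essentially certain.
* **Node risks**: subjects are routed to terminal nodes; the node with the
  lowest case fraction (ties to the larger node) is the reference; every
  other node gets a cross-product OR vs the reference, optionally a
  logistic-adjusted OR on node-indicator dummies plus covariates.
  Testing-set evaluations reuse the learning-set reference node. The
  learning/testing partition is a seeded, status-stratified 65/35 split.
* Surrogate splits, multiway splits and ensembles are out of scope.

## Synthetic cohorts

The generator draws a worker population and accrues a case-control sample:

* **Genotypes**: per SNP, P(BB)=q²+fq(1−q), P(AB)=2q(1−q)(1−f),
  P(AA)=p²+fp(1−p) with q the variant-allele frequency and f an
  inbreeding-style HWE departure (f=0 gives HWE, f=1 removes
  heterozygotes). SNPs are independent — no linkage disequilibrium.
* **Covariates**: age ~ N(48.32, 5.69) years; years of exposure ~
  N(12.24, 5.75) truncated above 3 years; SPL ~ N(85.79, 5.13) dB(A),
  calibrated once (numerically, against the truncated-years distribution)
  so the derived CNE has mean 96.51 and SD 5.49 dB(A)·years — the
  screening-stage moments of the study population this package models.
  PPE use, smoking and drinking are Bernoulli(0.70/0.45/0.40), plausible
  rates for male-dominated noise-exposed workforces; no published values
  pin them down.
* **Disease model**: logit P(case) = intercept + Σ effect codings × lnOR,
  plus optional interaction products (SNP × SNP or SNP × covariate
  threshold). The intercept is a free parameter (the study design carries
  no population prevalence); −1.0 by default. Cases and controls accrue by
  rejection sampling from this population model until the quotas fill —
  the simplest scheme under which crude ORs converge to the specified
  effects, since the odds ratio is invariant under outcome-dependent
  sampling. A draw budget guards against unreachable intercepts.
* **Defaults as study conditions**: two stages of 83/83 and 153/252
  subjects over a 60-SNP panel; six planted effects at the replication
  stage's crude ORs (recessive 2.261, recessive 1.861, dominant 1.639,
  recessive 2.659, super-dominant 1.437, dominant 1.550) on SNPs with
  common-variant frequencies 0.30–0.45. Audiometric thresholds are
  optional status-conditional Gaussians truncated into each class's
  defining region — they exercise the classifier, not audiogram realism.
* One master seed; per-stage and per-stream sub-seeds are fixed labeled
  spawns, so a whole two-stage study reproduces from a single integer.

What the generator does **not** emulate: LD between SNPs, age-dependent
audiograms, exposure-covariate correlations (age × years of exposure are
independent here), genotyping batch effects. Passing tests therefore
demonstrate correctness of the estimators under the assumed sampling
model, not robustness to those real-data features.

## Verification problem sizes

The test suite and the acceptance script size their simulations to the
study's own scales: HWE calibration at 252 controls (5000 replicates);
Woolf CI coverage at n = 2000 (1000 replicates); two-stage screen error
rates at 83/83 → 153/252 (200 seeds in tests, 100 in the script); GRS
dose-response at n = 4000 with per-allele OR 1.5 and risk-allele frequency
0.55 (the strongest validated SNP sits near 0.58, and common risk alleles
are what populate the upper GRS bins); CART interaction recovery at
n = 1000 with joint OR 6; null-tree collapse at 153/252. Published
worked-example odds ratios are recomputed from their printed marginal
counts exactly.

## Known limitations

* Adjusted ORs from the original individual-level data are not
  reproducible here (the data are access-controlled); the adjusted pipeline
  is validated by closed-form equivalence and parameter recovery on
  synthetic cohorts instead.
* Wald/Woolf intervals are first-order; exact or profile-likelihood
  intervals are not provided, and published CI digits computed with a
  different routine can differ in the third decimal even when ORs match.
* The CART learning/testing split and CV folds make tree topology
  seed-dependent in weak-signal regimes; only the seeded pipeline is
  reproducible, not tree stability across seeds.
* The trend test scores open-ended bins as ordinals; alternative scorings
  (bin midpoints, mean GRS per bin) change the statistic.
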