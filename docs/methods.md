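# Methods

## The two-stage screen

The package tests, for each SNP, whether genotype modifies the effect of a
randomized treatment on a binary outcome, using a matched case-control
sample nested in the trial cohort.

Stage 1 fits, per SNP, the logistic model

    logit Pr(case = 1) = α + β G + γᵀ x

on the full matched sample, where G is the minor-allele count (additive
coding, minor allele defined in the analyzed sample; inputs counting the
major allele are recoded with a log entry), and x collects confounders,
the variables used for matching, the randomization assignments of every
trial component, and the top k genotype principal components. SNPs with
two-sided p below the screen threshold (default 0.05) survive to stage 2.

Stage 2 uses only cases, separately within each of the two non-overlapping
hormone-trial components. Randomization makes assignment Z independent of
G in the source population, so any dependence of Z on G among cases is
evidence of interaction. The model is

    logit Pr(Z = 1 | G) = log(q / (1 − q)) + β₀ + β₂ G

with q the design fraction assigned to active treatment — a known constant
supplied in configuration and never estimated from the cases (estimating it
would absorb part of the treatment main effect into β₀ and bias the test).
The 1-df likelihood-ratio statistics for β₂ = 0 from the two trials are
summed into a 2-df chi-square statistic; equivalently, two independent
p-values are combined by converting each to its chi-square(1) quantile,
summing, and evaluating the chi-square(2) upper tail. BH step-up FDR (and
Bonferroni, for reference) are computed over the stage-1 survivors only.
This restriction is valid because the stage-1 (prospective, case-control)
and stage-2 (retrospective, case-only) statistics are asymptotically
independent — a property verified empirically in the acceptance suite.

Assumptions worth stating explicitly:

- **Gene–environment independence** holds by randomization; the case-only
  test is not valid for observational exposures without it. Observational
  (OS) subjects contribute to stage 1 only.
- **Rare outcome.** β₂ approximates the interaction log odds ratio of the
  disease model; the approximation error is O(disease probability) and is
  negligible at the outcome rates simulated here (≤ 5%).
- The case-only models contain only G; covariates do not enter stage 2.
  Covariate support is deliberately absent rather than unimplemented.

## Follow-up and discrimination

For flagged SNPs the package reports, per trial and per stroke-subtype
scope ("all" includes the unclassified "other" category):

- **Genotype-stratified treatment odds ratios** at 0/1/2 minor alleles:
  or(g) = (a/b)/(q/(1−q)) from treated/placebo case counts a, b, with Wald
  CI exp(log or ± z·√(1/a + 1/b)). A cell with a = 0 or b = 0 is reported
  NA (counts still shown); no continuity correction is applied. These raw
  ratios coincide exactly with the exponentiated coefficients of an offset
  logistic fit on genotype-level indicators with no intercept — a tested
  invariant, which is why the two parameterizations are interchangeable.
- **1-df and 2-df interaction LRTs** (linear allele count vs indicators for
  one and two minor alleles). When a genotype cell is empty the indicator
  model loses that column and the nominal 2-df test collapses to the
  remaining degrees of freedom; with one contrast left the two tests
  coincide exactly. A one-armed (all-treated or all-placebo) cell separates
  the fit; its log-likelihood still converges to a finite limit, and the
  reported statistic is that limiting deviance while the OR cell itself is
  NA.
- **Joint two-SNP case-only models**, additive (1-df per SNP, "monotone"
  interaction) or indicator coding (2-df), with per-SNP tests dropping only
  that SNP's terms. Perfectly correlated genotypes are rejected as
  collinear; the pipeline picks at most one representative per LD cluster
  (r² < 0.8) when choosing SNPs for the joint model and the risk-model
  extension.

Discrimination is summarized by apparent (in-sample) AUC — Mann–Whitney
concordance of fitted risk scores, ties counting one half — for a covariate
base model versus the same model extended with SNP genotype indicators and
their products with the hormone-trial assignment. The bootstrap resamples
matched pairs as units (preserving the 1:1 design), refits both models per
replicate, and reports a percentile CI for the AUC difference and a
two-sided p from a normal approximation to the bootstrap distribution
(default B = 1000 in the API, 200 in the pipeline preset runs; replicates
with separated or rank-deficient refits are dropped and counted). Apparent
AUC is optimistic for SNPs selected in the same data; the test suite
demonstrates the apparent-vs-split-sample gap rather than correcting it.

## Synthetic data generator

The generator emulates the study design so that every stage is testable
without access to trial data:

- **Cohort**: postmenopausal women split into observational and
  clinical-trial arms; CT members join a hormone-therapy and/or dietary
  component (all CT members join at least one) with later randomization
  into a calcium/vitamin-D component ("partial factorial"). Hysterectomy
  routes HT members to the E-alone trial, others to E+P. Defaults: 25% OS,
  35% hysterectomy prevalence, 40%/70%/55% HT/DM/CaD participation,
  q = 0.5 for the hormone trials and CaD, q = 0.4 for DM. Covariates (age
  uniform 50–79, smoking 50/40/10% never/past/current, diabetes 6%,
  hypertension 35%, aspirin 20%, statin 12%, prevalent stroke 1.5%,
  physical functioning ≈ N(85, 15) clipped to [0, 100]) are plausible
  defaults for such a cohort, not estimates of any particular study.
- **Genotypes**: Balding–Nichols structure — per subpopulation the allele
  frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) around base MAF p with
  differentiation F; genotypes are Hardy–Weinberg within subpopulation.
  Two subpopulations (80/20) by default, with ethnicity tied to
  subpopulation so PCs have a real confounder to absorb. High-LD pairs are
  generated by haplotype copying: each partner allele is retained with
  probability √r²* and redrawn otherwise, giving genotype r² ≈ r²*
  (exact copy at r²* = 1).
- **Outcomes**: stroke is Bernoulli of a logistic score with baseline,
  covariate, SNP-marginal, treatment-main and SNP×treatment terms; subtypes
  (ischemic/hemorrhagic/other, default 66/17/17%) are multinomial among
  cases; event year uniform over a 9-year follow-up window.
- **Matching**: greedy one-to-one nearest-age matching within exact strata
  of the categorical factors (ethnicity, cohort, component memberships,
  hysterectomy, prevalent stroke), age caliper 2 years, follow-up time in
  1-year bands of a reference year (event year for cases, a random at-risk
  year for non-cases). Cases are processed in seed-randomized order;
  controls are used at most once; unmatchable cases are dropped and
  reported.

What the generator does **not** emulate: realistic human LD maps beyond the
planted pairs, genotyping error and missingness mechanisms beyond missing
completely at random, time-to-event structure (the analysis is
case-control, not survival), and between-region LD. Passing tests
demonstrate the statistical behavior of the screen under its stated
assumptions, not robustness to violations absent from the generator.

### Presets

- `tiny` — 200 subjects, 10 SNPs; a smoke fixture (its matching strata are
  coarsened because 200 subjects cannot fill the full stratification).
- `null` — treatment main effect OR 1.4, one SNP with marginal OR 1.2, all
  interactions zero: the calibration condition for type-I-error and
  uniformity checks.
- `f13a1_like` — 9,000 subjects, 50 SNPs including a MAF 0.09 pair at
  r² ≈ 0.985 whose minor allele attenuates the E+P effect (interaction
  log-OR −0.9, E-alone −0.4). The planted marginal OR is 1.6 — larger than
  a full-scale study would show — because the preset runs at roughly 600
  matched pairs rather than thousands and exists to exercise the screen's
  power path at desk scale.
- `pcsk9_like` — as above with a common (MAF 0.34) pair and opposite-sign
  interactions across the two trials.

## Numerical choices

- **Logistic ML**: Newton–Raphson/IRLS with step-halving; convergence when
  the maximum absolute score < 1e-8 or the relative log-likelihood change
  < 1e-10; at most 100 iterations. Covariance is the inverse observed
  information at the optimum. Any |coefficient| > 15 at termination, or
  hitting the iteration cap, flags the fit (quasi-complete separation);
  consumers report NA rather than a spurious p. Cross-checked in tests
  against grid-search maximization and statsmodels GLM.
- **Chi-square tails/quantiles** via scipy (regularized incomplete gamma).
- **Stage-1 p-value**: two-sided Wald on the genotype coefficient by
  default — the conventional scan statistic, cheaper per SNP; a 1-df LRT is
  available by flag. Missing genotypes are complete-case per SNP; missing
  covariates complete-case with a logged count.
- **Genotype PCA**: per-SNP mean imputation, columns standardized
  (monomorphic columns dropped, logged), SVD; sign fixed so each
  component's first nonzero loading is positive. The pipeline LD-prunes the
  panel (r² < 0.2, echoing a panel designed with low between-region LD)
  before PCA: on small panels a high-LD pair otherwise contributes a
  principal component of its own and the adjustment would absorb the very
  SNP under test.
- **BH with a family larger than the supplied p-values**: adjusted values
  are computed from the supplied (smallest) members; the unsupplied members
  are assumed no smaller than the largest supplied value, and the output
  flags which entries are provably unaffected by that assumption (those
  with adjusted value ≤ max supplied p). This is what lets the FDR column
  of a published top-10 be reconstructed exactly at its small ranks.
- **Seeds**: a master seed spawns per-stage child seeds through numpy's
  SeedSequence in fixed stage order, so each stage is independently
  reproducible and pipeline reruns are byte-identical.

## Problem sizes in the test suite

Calibration and power checks run at deliberately modest sizes chosen to
make Monte-Carlo error small relative to the tested tolerance: 5,000
replicates (~320 cases each) for the 2-df type-I error band [0.04, 0.06];
2,000 replicates for stage-independence (|r| < 0.06 ≈ 3 MC standard
errors); 500 shared datasets for the efficiency comparison; 500 replicates
at 450 cases for recovery of an interaction log-OR of −0.8 (mean within
±0.1, coverage within [0.92, 0.98]). Oracle-equivalence checks (grid
search, brute-force BH, all-pairs AUC) are exact to the stated numerical
tolerances.

## Known limitations

- Winner's curse: effect estimates for SNPs selected by significance rank
  are exaggerated; the package documents this and does not correct it.
- Matching variables enter stage 1 as regression covariates, mirroring the
  analysis design; conditional logistic regression is out of scope.
- The 2-df combination supports exactly two trial components; extending to
  more components is an architectural possibility, not an implemented one.
- Sparse strata (notably hemorrhagic subsets) produce NA cells and
  collapsed tests by design; no small-sample corrections are applied.
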