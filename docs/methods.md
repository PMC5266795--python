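# Methods

This note records the statistical model the package implements, the
assumptions behind the synthetic-data generator, the numerical conventions,
and the design choices made where the design was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The inference chain

The estimand is theta: the effect of a 1 mmol/L *lower* LDL cholesterol
concentration — as produced by variation in the target gene — on each
outcome (trait units for continuous outcomes, log-odds for type 2
diabetes). The chain is strictly ordered:

1. **Study level.** Per (study, SNP, trait): additive per-allele linear or
   logistic regression, dosage = count of LDL-lowering alleles (records
   supplied in the opposite orientation are recoded `g -> 2 - g`).
2. **Quality filters.** A 1-df chi-square Hardy-Weinberg test per
   (study, SNP); pairs below the threshold (default p < 1e-6) are removed
   from *all* trait pooling for that pair, with every removal logged. For
   binary outcomes, fits with any genotype-by-outcome cell below 5 are
   flagged and excluded from pooling (rare-allele separation guard).
3. **Level-1 pooling.** Per SNP and trait, inverse-variance weighted
   fixed-effect pooling across studies (and consortium records after
   provenance-based overlap exclusion), plus DerSimonian–Laird random
   effects; Cochran's Q, I², and the one-sided upper 97.5% I² bound.
4. **Wald scaling.** Each SNP's pooled outcome association is divided by
   the absolute value of that SNP's *own* pooled fixed-effect LDL
   association; standard errors divide by the same quantity (variance by
   its square — the first-order delta-method result with the denominator
   treated as fixed). A configurable `ratio_variance` flag adds the
   second-order denominator-uncertainty term for sensitivity; it is off by
   default, matching the fixed-denominator convention.
5. **Level-2 pooling.** IVW combination of the scaled SNP estimates into
   the gene-centric score, fixed and random effects, with between-SNP
   heterogeneity. Binary traits are additionally reported as odds ratios.

Identifying assumptions (standard MR): the variants affect the outcomes
only through LDL (no horizontal pleiotropy — true by construction in the
generator), are unconfounded, and are strong enough instruments for the
ratio's delta-method normal approximation.

## The synthetic world

The generator's defaults are the stated conditions of the analysis it
emulates, not tuning knobs.

* **Instruments.** Four SNPs with minor allele frequencies 0.14, 0.01,
  0.36, 0.17 and per-allele LDL effects (-0.02, -0.34, -0.06, -0.10)
  mmol/L. The first two LDL effects are published per-allele estimates;
  the last two are placeholders on the same scale (the source prints them
  only graphically) and are never asserted as reference values.
* **Genotypes.** Gaussian copula: each dosage is a double-thresholding of
  a latent standard normal, thresholds giving the (optionally inbred)
  Hardy-Weinberg genotype frequencies (heterozygote share 2pq(1-F)); the
  latent pairwise correlation is solved by root-finding so the realised
  genotypic r² hits its target, with an explicit error when a target
  exceeds the copula-attainable bound for the two allele frequencies, and
  a generation-time check that realised correlations respect that bound.
  The *default* LD matrix is the identity: the instruments were selected
  for approximate independence, and any materially correlated pair of
  causal SNPs would shift marginal per-allele effects away from their
  published values by construction. The residual-LD regime (maximum
  r² 0.26 between the two common SNPs) ships as
  `ld_sensitivity_config()` and drives the LD-correction diagnostic.
* **Mediation.** `LDL = 3.50 + sum_j beta_j g_j + N(0, 0.85)` mmol/L;
  the intercept 3.50 puts the population mean at ~3.41 mmol/L after the
  allele effects. Continuous traits:
  `Y = baseline + theta * (3.50 - LDL) + N(0, sd)`; diabetes:
  `logit P(case) = -2.30 + theta_D * (3.50 - LDL)` (baseline prevalence
  ~9.1%). Cases are flagged prevalent with probability 0.5. Defaults for
  theta are the published per-1-mmol/L estimates: glucose 0.09 mmol/L,
  HbA1c 0.03%, log-insulin 0, weight 1.03 kg, height 0.008 m, WHR 0.006,
  diabetes log-odds ln(1.29).
* **Derived traits.** Weight and height are simulated with their own
  theta; BMI is computed as weight/height², which reproduces the observed
  attenuation of the BMI effect relative to bodyweight (the height effect
  subtracts roughly 2·BMI/height · theta_height). Fasting insulin lives on
  the natural-log scale so its effect reads as a percent difference.
* **Chosen constants** (no stated source; fixed once as realistic adult
  European-ancestry values and not revisited): trait noise SDs glucose 0.8
  mmol/L, HbA1c 0.5%, log-insulin 0.6, weight 15 kg, height 0.09 m,
  WHR 0.08; baselines glucose 5.38 mmol/L, HbA1c 5.50%, weight 78 kg,
  height 1.69 m, WHR 0.87; fasting fraction 0.7 (glucose and insulin are
  analysed in fasting-flagged individuals only); default world 20 studies
  of 10 000.
* **What the generator does not emulate**, hence what a green test does
  not establish: between-study heterogeneity in baselines or effects
  (every study shares one data-generating process, so heterogeneity
  statistics are exercised under their null), population stratification
  and ancestry structure, horizontal pleiotropy (a knob exists in the
  design but defaults to zero), genotyping error beyond the inbreeding-F
  HWE violation, informative missingness, and survival time for incident
  cases (the incident/prevalent flag is a label, not a time axis).

## Numerical conventions

* OLS via the closed-form normal equations; logistic fits by
  Newton–Raphson/IRLS, converged when max |score| < 1e-8 or the relative
  log-likelihood change < 1e-10, at most 50 iterations; |coefficient| > 15
  raises an explicit separation error. Both are cross-checked in tests
  against statsmodels and a derivative-free optimiser.
* All confidence intervals use the normal 97.5% point 1.959964; no
  small-sample t adjustment (large-sample genetic-epidemiology practice).
* I² upper bound: test-based interval on ln H with
  `se(ln H) = (ln Q - ln(k-1)) / (2(sqrt(2Q) - sqrt(2k-3)))` for Q > k,
  else `sqrt(1/(2(k-2)) (1 - 1/(3(k-2)^2)))`; undefined (reported absent)
  for k = 2 with Q <= k; floored at I² itself.
* Random effects: DerSimonian–Laird moment estimator only.
* Fisher's method clips p = 0 to the smallest positive float with a
  warning; the HWE test floors p at 1e-300 so the (0, 1] invariant holds.
* Dose–response: weighted Pearson correlation and weighted-least-squares
  slope with k-2 error degrees of freedom (t-based CI and p). With the
  LDL-lowering orientation, proportionality appears as r near -1.
* Degenerate inputs are errors with named culprits (constant dosage,
  monomorphic SNP, missing genotype class, rank-deficient design,
  ambiguous overlap provenance), never silent NaNs.
* Pipeline outputs serialise floats at 6 significant digits,
  round-half-even; a single run seed expands into per-study/per-stage
  substreams via `default_rng([seed, stream, study])`, so adding a study
  never perturbs another study's draws.

## Open design choices, resolved

* **Variance scaling exponent.** The scaled variance uses the *squared*
  inverse of the LDL effect. Multiplying a variance by the unsquared
  inverse is dimensionally incoherent; the squared form is the
  delta-method result and makes scale-then-unscale an exact round trip.
* **Scale-then-pool order.** Each SNP is scaled by its own pooled LDL
  effect before cross-SNP pooling (the per-SNP scaled estimates are
  themselves reportable rows); pooling per-allele estimates first and
  scaling by a score-level LDL effect is not implemented.
* **HWE test and threshold.** 1-df chi-square (not the exact test) with
  default exclusion at p < 1e-6 — conventional GWAS practice; the
  threshold is configurable because the emulated analysis did not publish
  its exact value.
* **Covariates.** Study-level fits are crude per-allele models (no
  age/sex adjustment), the simplest reading of a shared analysis script;
  the model surface accepts pre-constructed cohort frames, so adjusted
  residuals can be supplied upstream if needed.
* **Stratified analyses** keep all non-cases as the comparison group in
  both the incident and prevalent strata; controls are not split.
* **Coverage experiment configuration.** The CI-coverage suite uses a
  3-SNP small world that drops the weakest instrument (per-allele LDL
  effect -0.02 mmol/L): at the small-world sample size its first-stage
  t-statistic is about 2, and delta-method Wald intervals are known not to
  be calibrated for weak instruments. This is a precondition of the
  method, decided from the first-stage power calculation, not from test
  outcomes.

## Known limitations

* The Wald ratio's fixed-denominator variance understates uncertainty
  when instruments are weak; the `ratio_variance` flag exists but the
  default mirrors the emulated analysis.
* With an r²=0.26 pair of causal SNPs, univariable and multivariable
  per-allele estimates *must* differ systematically (marginal vs
  conditional regression coefficients); agreement between the two analyses
  is expected — and tested — on the per-1-mmol/L scale, where both target
  theta. Row-wise agreement within one univariable SE is not attainable at
  any sample size because the difference of the two estimators carries
  irreducible relative sampling variance R²/(1-R²); one acceptance test
  documents this and is expected to fail.
* No meta-regression, publication-bias diagnostics, MR-Egger/weighted
  median estimators, survival modelling, or genotype imputation.
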