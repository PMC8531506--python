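# Methods

## Model

The observation model for individual `i` at age `t` (days) is a logistic
growth curve with individual-level random deviations on the mature weight
`A` and the maturity rate `K`:

```
w_it = A_i / (1 + b * exp(-K_i * t)) + e_it
A_i = x_i' beta_A + eps_Ai
K_i = x_i' beta_K + eps_Ki
(eps_Ai, eps_Ki) ~ N2(0, Sigma),   e_it ~ N(0, s2_e)  i.i.d.
```

The fixed-effect design `x_i` holds an intercept, sex (0/1) and the top
five principal components of the standardized genotype matrix; in the SNP
models the mean-centered additive dosage (0/1/2 copies of the alternate
allele) joins both predictors (M1), the `A` predictor (M2) or the `K`
predictor (M3).  Covariates are mean-centered so the intercepts are the
population means `mu_A` and `mu_K`.  The time-scale `b` is a single shared
parameter: it carries no covariates and no random effect.  `Sigma` may be
singular or zero; `s2_e > 0`.

There is no polygenic/genomic-relationship random effect: the population
modelled is a crossbred cohort without pedigree, and population structure
is absorbed by the PC covariates.

## Likelihood approximation

The marginal likelihood integrates `(eps_A, eps_K)` out of a nonlinear
mean, which has no closed form.  We use the first-order conditional
(Lindstrom–Bates / FOCE) approximation: for each individual the penalized
conditional mode of the whitened random effect `u` (`eps = L u`,
`Sigma = L L'`) is found by damped Gauss–Newton (2x2 solves, vectorized
across individuals and across candidate parameter vectors), and the mean is
linearized there, giving per individual a closed-form Gaussian term with
covariance `s2_e I + J Sigma J'` evaluated by the Woodbury identity.  With
`Sigma = 0` the expression reduces *exactly* to the i.i.d. Gaussian
nonlinear-regression log-likelihood.

The parameterization used by the optimizer is unconstrained: the Cholesky
factor of `Sigma` (raw entries, so a zero variance is attainable), `log b`
and `log sigma_e`.  Internally weights are scaled by the mean weight and
ages by the mean scheduled age so that every free parameter is O(1);
log-likelihoods are reported on the gram scale.  Overflowing exponentials
are clipped and non-finite objectives replaced by a large penalty so line
searches can retreat.

Fitting maximizes the FOCE log-likelihood with L-BFGS-B over all parameters
jointly — maximum likelihood throughout, never REML, so likelihood-ratio
tests between models that differ in fixed effects are valid.  Gradients are
batched central finite differences (step `1e-4 * max(1, |theta|)`); the
conditional modes are cached between objective calls, which makes the inner
Gauss–Newton converge in a handful of iterations after the first call.
Convergence is L-BFGS-B's relative-improvement test (`ftol = 1e-10`) or
projected gradient below `1e-5`; hitting the 200-iteration cap flags the
fit as non-converged rather than raising.  Per-SNP fits warm-start from the
null-model optimum with zero SNP coefficients.

An adaptive Gauss–Hermite quadrature implementation of the same integral
(grid centered at the conditional mode, scaled by the Gauss–Newton
curvature; degenerate `Sigma` directions handled by integrating only the
non-null eigen-directions) serves as an independent numerical oracle in the
tests.  On the standard 5-individual fixture the FOCE value is within 0.09
of the 21-node oracle, and doubling the node count moves the oracle by less
than 1e-4.

## Testing SNPs

The null model M0 is fitted once per cohort and reused for every SNP (it
contains no SNP term, so it is SNP-invariant).  The LRT statistic
`2 (logLik_alt - logLik_0)` is clamped at zero and referred to chi-square
with df equal to the parameter-count difference — 2 for M1, 1 for M2/M3
under additive dosage coding.  Additive coding (one coefficient per
targeted parameter) is the conventional GWAS choice; a 2-df genotype-class
coding would change the df bookkeeping but nothing else in the machinery.
Non-convergent per-SNP fits yield a missing p that propagates to a missing
q and is excluded from the FDR input.  SNPs with missing dosages either
raise (default; impute first) or, with `on_missing_dosage="refit"`, are
tested on the complete-genotype subset against a null refitted on that same
subset so the comparison stays nested.

FDR is controlled per hypothesis family (M1, M2, M3 each get their own
q-values, mirroring separate Manhattan panels).  Storey's pi0 is estimated
on the lambda grid 0.05..0.90 (step 0.05) with a cubic-polynomial smoother
evaluated at the largest lambda; the q-value is the monotone tail minimum
of `pi0 * m * p / rank`.  With fewer than 100 p-values, or an estimate
outside [0.1, 1], the method falls back to Benjamini–Hochberg (pi0 = 1)
with a warning; Storey with pi0 = 1 coincides with BH exactly.
Significance is strict: q < 0.05.

## Growth-curve screening

Model selection across the five families (logistic, Gompertz, Brody,
Von Bertalanffy, Richards) is done on population-level pooled records by
least squares with analytic Jacobians: the screening question is the
*family ranking*, and the full mixed model is refitted for the chosen
family in the GWAS stage anyway.  AIC/BIC use the Gaussian ML
log-likelihood with the residual variance counted as a parameter; the
selected model is the converged fit with the lowest AIC, ties broken by BIC
and then by parameter count.  Richards is implemented as
`A (1 + s*b*exp(-Kt))^m` with a sign switch `s` (default −1, making Brody
and Von Bertalanffy special cases; `s=+1, m=-1` is the logistic).  Its
shape parameter is weakly identified on near-logistic data and the fit may
legitimately end non-converged (runaway `m` or boundary `b` are flagged);
`select_model` simply excludes it then.  Starting values: `A0 = 1.1
max(w)`; `K0` and `b0` from a family-specific log-linearization.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets:

- schedule 35, 42, 49, 56, 63, 70, 84 days of age;
- `mu_A = 2615.45` g, `mu_K = 0.054`/day; `mu_b = 15.35`, solved so the
  mean curve passes through the day-35 population mean of 788.05 g;
- `sigma_A = 210` g (CV ~8% of `mu_A`) and `sigma_K = 0.0054` (CV ~10%),
  `sigma_AK = 0`, `sigma_e = 60` g.  No variance components are reported
  for the reference population, so these are plausible stand-ins chosen
  once: coefficients of variation of individual growth parameters in meat
  livestock are typically near 10%, and a 60 g weighing error is a few per
  cent of mid-trajectory weight.  Sex effects default to zero.
- independent Hardy–Weinberg SNPs at MAF uniform in [0.05, 0.5].  LD is
  *not* simulated (the scan targets an LD-pruned panel); duplicate-column
  injection is available for LD-pruning tests.  Optional island-model
  structure draws subpopulation allele frequencies from a Balding–Nichols
  Beta with F_ST = `subpop_divergence` (default off).
- optional additive SNP effects on `A` and/or `K`; realized per-individual
  `(eps_A, eps_K, A_i, K_i)` are returned as ground truth.
- a corruption stage injects, at configurable rates, exactly the artifacts
  the phenotype QC removes: values displaced 8 time-point SDs from the
  day mean, >5% decreases between consecutive records (new value 80–90% of
  the previous one), and missing records — with a manifest for
  QC-sensitivity tests.

What the generator does not emulate: real LD structure, genotyping error,
non-Gaussian residuals, heteroscedastic weighing error, age-dependent
variance, or selection/attrition over time.  Passing tests therefore
demonstrate correctness of the machinery under the model's own assumptions,
not robustness to their violation.

## QC conventions

Phenotypes: (1) per weighing day, records beyond 3 sample SDs of that day's
mean are masked, with mean/SD computed once before masking (a single
screen, not iterated — hence rerunning QC can in principle expose one more
borderline record; the tests assert monotonicity rather than bit-identical
idempotence); days with fewer than two records skip the rule with a
warning.  (2) scanning in time order, a record below 95% of the nearest
earlier *surviving* record is masked — the nearest-survivor reading is the
conservative resolution of "consecutive" once gaps exist.  (3) individuals
with strictly more than two missing records are removed.  Order fixed:
outliers → decrease → drop.  QC only masks or drops, never edits values.

Genotypes: filters use strict inequalities (missing rate < 0.1 per SNP,
< 0.2 per individual, MAF > 0.05, HWE exact p > 1e-8) in the order SNP
call rate → individual call rate → MAF → HWE.  The HWE test is the
two-sided conditional exact test (probabilities of heterozygote counts no
more likely than observed, given allele counts).  Missing genotypes are
imputed by sampling each SNP's observed genotype frequencies — a
deliberately simple single-marker imputer, sufficient because imputation
only feeds LD pruning and PCA and scan SNPs are near-complete post-filter.
LD pruning is greedy left-to-right within chromosome with a 50-SNP
lookahead window on dosage r^2 > 0.9 (the window is a pragmatic bound on
the pairwise work; r^2 and window size are conventional choices).  PCA
standardizes dosage columns (zero-variance columns dropped) and reports
each component's share of total variance.

QTLs: clusters are runs of significant SNPs with inter-SNP gap <= 100 kb
(single linkage on positions), each spanning +/-100 kb beyond its extreme
members, floored at base 1.  Gap-based linkage rather than interval
merging is deliberate: it can produce overlapping QTL intervals listed as
distinct, which is the behaviour reported in practice.  Coordinates are
1-based inclusive end-to-end; BED export converts to 0-based half-open.
SNP location classes are hierarchical (5'-UTR, 3'-UTR > exon > intron >
intergenic) over any overlapping transcript, strand-agnostic.

## Problem sizes used by the test suite

Stochastic checks run at sizes chosen to make the assertions sharp while
keeping the suite practical: parameter recovery and model screening use
400-individual cohorts (50 replicates for the AIC ranking); the null
calibration of the M1 LRT uses one 200-individual cohort and 1000
independent null SNPs (type-I error asserted in [0.03, 0.07] at alpha =
0.05 — the FOCE LRT runs mildly anticonservative at this sample size, which
the band accommodates — plus a KS uniformity check); FDR/power behaviour
uses smaller pooled panels.  All simulations are seeded; hypothesis-based
property tests are derandomized.

## Known limitations

- FOCE is an approximation; its LRT is slightly anticonservative at
  moderate n (observed type-I ~0.065 at n=200) and variance components
  near zero sit on the boundary of the parameter space, where chi-square
  reference distributions for *variance* tests would not apply (only fixed
  effects are tested here).
- Finite-difference gradients cost (2P+1) objective evaluations per
  iteration; the scan is ~0.4 s per SNP-model at n=200 on one core.
  Analytic gradients would be the next optimization.
- The pooled growth-curve screen ignores the random effects, so its
  absolute AIC values are not comparable to mixed-model AICs — only the
  within-screen ranking is used.
- GO/KEGG enrichment and haplotype-model imputation are out of scope.
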