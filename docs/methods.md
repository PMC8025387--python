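# Methods

This note documents the models, numerical choices and known limitations
of `ewasmed`. Notation: β is the methylated fraction at a CpG in [0, 1];
M = log₂(β/(1−β)) is the analysis scale; T a binary treatment exposure;
Y a binary chronic health condition (CHC).

## Preprocessing model

**QC filters.** An entry with detection p > 0.01 is set missing. Samples
with more than 5% missing entries are removed first, then probes with
more than 5% missing among the retained samples. Sample-first ordering is
deliberate: a failed sample should not drag otherwise-good probes below
the threshold. The filter is idempotent.

**Quantile normalization.** Every sample is mapped onto the pooled mean
quantile function: each sample's sorted unmasked values are interpolated
onto a common probability grid (one point per CpG) and averaged across
samples to form the reference; each sample's values are then replaced by
the reference quantile at their within-sample rank. For complete data
this is exactly the classical mean-of-order-statistics scheme; with
missing entries the interpolated form is used because requiring CpGs
complete in *every* sample is hopeless at realistic failure rates
(0.99ⁿ of probes for n samples). Ties receive the mean of their tied
quantiles, making the map deterministic and rank-preserving.

**β↔M.** M = log₂(β/(1−β)) with the exact inverse. β ∈ {0, 1} is
rejected with an instruction to clip upstream; the simulator and pipeline
clip β to [0.001, 0.999], bounding |M| ≈ 9.96.

**Leukocyte deconvolution.** Per sample, nonnegative least squares of
the observed β values on cell-type reference β profiles (six blood cell
types by default), renormalized to sum to one. NNLS + renormalization
agrees with the equality-constrained quadratic program in the noise-free
limit and avoids a QP dependency. On simulated Dirichlet mixtures the
recovered weights are exact (< 1e−6) without noise and off by < 0.05 at
M-scale noise sd 0.3 with 600 reference CpGs.

**Methylation PCA.** Samples over CpG features, per-CpG mean-imputed and
centered, via SVD. The retained dimension k is the argmax of the relative
eigenvalue drop (λᵢ−λᵢ₊₁)/λᵢ within the first k_max (default 10),
falling back to min(4, available) when the profile is flat. The drop rule
operationalizes the informal "change rate of eigenvalues" criterion used
in practice; k = 4 is the conventional fallback for blood methylation.

## Treatment EWAS

Per CpG, OLS of M on exposure + covariates, two-sided t-test on the
exposure coefficient, complete-case per CpG on the missingness mask. CpGs
with rank-deficient designs or a constant exposure among complete cases
are flagged NA and the scan continues. CpGs are grouped by missingness
pattern so the common no-missing case is one batched linear solve.

**Adjustment-set rule.** The phi coefficient between binary exposures is
the 2×2-table correlation, with p from χ² = n·phi² (1 df). A co-treatment
is excluded from the adjustment set exactly when phi > 0.4 *and*
p < 0.05: adjusting for a near-collinear co-exposure would absorb the
very signal being tested. One cell-proportion column (the largest
subtype, neutrophils) is dropped to break the sum-to-one collinearity.

**Genomic control.** λ = median(χ²₁(p_raw)) / χ²₁-median₀.₅ (the null
median 0.4549 is computed from `scipy.stats.chi2.ppf(0.5, 1)`, not
hard-coded). When λ > 1 all statistics are deflated by λ and p recomputed;
λ ≤ 1 is reported but never used to inflate significance. The median form
is used rather than a regression-based λ. With fewer than 100 finite
p-values λ is unstable; the package warns and proceeds rather than
refusing, so small simulated panels remain analyzable. At desk scale the
chain runs with a few thousand CpGs and covariates *estimated from the
same matrix* (cell proportions, methylation PCs), which absorbs a little
per-CpG noise; realized λ on null panels is therefore mildly conservative,
typically 0.92–1.01 rather than centered exactly at 1.

**Significance.** Hits are p_gc < 9×10⁻⁸, strictly; a p exactly at the
threshold is not a hit.

**Dose–response.** Exposed doses are cut at tertiles (≤-inclusive upper
boundaries, boundary ties to the lower bin) and coded 0 (unexposed) /
1/2/3; the trend p is the t-test on the ordinal code's coefficient, with
"dose-responsive" meaning trend p < 0.05.

**Paired contrasts.** Both-vs-neither restricts to samples concordant for
the pair, removes the two treatments from the covariates, and requires at
least 10 samples per group.

**Enrichment.** Hits are compared against the whole tested background
("array content") per CpG-island category and functional region:
table [[hits in, hits out], [background in, background out]], sample OR
ad/bc plus the conditional-MLE OR and two-sided Fisher p, BH-FDR across
categories.

## CHC association

Residual M = M minus the OLS fit on sex, age, leukocyte proportions and
the genetic/methylation PCs — *not* the treatments, so treatment-driven
variation survives into the residual. Each residual is tested against
incident CHC status (prevalent cases excluded from the risk set;
a missing onset-timing flag excludes the sample with a warning) by
maximum-likelihood logistic regression adjusted for age, sex and the
CHC-specific PRS, Wald p on the residual-M coefficient, BH-FDR across
CpGs. Non-convergence and (quasi-)separation (|coef| > 50) are flagged NA
rather than reported. Wald rather than likelihood-ratio tests are used,
matching common EWAS-follow-up practice. Incidence summaries report
100·incident/at-risk rounded to one decimal with a Wald binomial CI by
default (Wilson et al. available via `ci_method`); the CI method used for
the published cohort intervals is not recoverable from the printed
numbers, so only point percentages are treated as reproducible.

## Polygenic risk scores

Greedy pruning in panel order: keep a SNP iff its squared Pearson
correlation with every kept SNP is < 0.3, computed from the supplied
dosage matrix (never an external LD panel). Input order is part of the
contract — permuting it may change the retained set. Monomorphic SNPs
(undefined r²) are dropped with a warning. The score is the unweighted
sum of risk-allele dosages over retained SNPs, mean-imputing missing
dosages per SNP.

## Mediation

Two models on the incident risk set:

* mediator (linear): M_resid ~ T + other significant treatments;
* outcome (logistic): Y ~ T + M_resid + age + sex + PRS + other
  significant treatments,

where "other significant treatments" are those with p < 0.05 in a
one-shot multivariable logistic of the CHC on all treatments + age + sex,
additionally filtered by the phi-exclusion rule relative to T.

The quasi-Bayesian estimator draws n_draws parameter vectors from
N(MLE, cov) of each model. Per draw, counterfactual mediator values
M(0), M(1) are the mediator-model predictions plus a residual-error draw
ε ~ N(0, σ̂²); the *same* ε is shared between the two arms per
(draw, sample). Sharing cancels in M(1) − M(0), so the mediated contrast
is estimated with far less Monte-Carlo noise, and in the identity-link
limit each draw's ACME reduces exactly to a_draw·b_draw, making the
product-of-coefficients closed form the natural oracle. Potential outcome
probabilities are averaged over samples:

* ACME(t) = E[Y(t, M(1)) − Y(t, M(0))], ADE(t) = E[Y(1, M(t)) − Y(0, M(t))],
* reported ACME/ADE = averages over t ∈ {0, 1}; total = ACME + ADE
  (an identity per draw, asserted within 3 MC standard errors on every
  result); proportion mediated = ACME/total.

Effects are on the risk-difference (probability) scale; the total effect
is additionally expressed as the treatment OR from the outcome model
without the mediator. Percentile (not bias-corrected) 95% intervals; the
ACME p is the two-sided tail fraction of the draw distribution, floored
at 1/n_draws. n_draws defaults to 1000 and values below 100 are
rejected. A proportion mediated outside [0, 1] (ACME and direct effect of
opposite sign) is reported unclamped with a warning — clamping would hide
the pathology. Mediator selection is BH-FDR over candidate CpGs within a
(treatment, CHC) pair at q = 0.05; pruning sorts survivors by ACME
descending (ties lexicographic by CpG id) and keeps a CpG iff residual-M
r² < 0.05 with everything kept, and the combined score is the plain sum
of the retained residual M values (samples missing any constituent drop
out, logged).

## Synthetic cohorts

The generator reproduces the structure the analysis assumes, with ground
truth for every quantity it hides:

* **Treatments.** A latent multivariate Gaussian thresholded at
  Φ⁻¹(1−prevalence); each target phi is converted to a latent correlation
  by numerically inverting the bivariate-normal orthant probability
  (Brent's method on [−0.999, 0.999]). This gives exact marginals with
  controllable phi; an infeasible phi structure (non-PSD latent matrix)
  raises an error naming the worst pair.
* **Methylation.** β = (Dirichlet cell proportions) × (cell-type
  reference β profiles); treatment effects are injected as shifts δ on
  the M scale at designated causal CpGs (the analysis scale, so δ is
  directly comparable to EWAS coefficients); Gaussian M-scale noise;
  β clipped to [0.001, 0.999]; detection p ~ U(0, 0.01) with failures
  > 0.01 at a configurable rate. The default blood-like Dirichlet
  α = (20, 3, 3, 5, 2, 2) is neutrophil-dominated with realistic spread.
* **Outcomes.** P(Y=1) = expit of intercept + treatment terms + mediator
  terms on residual M (M minus the cell-mixture baseline — exactly the
  injected shift plus noise) + age/sex/PRS terms; a configurable fraction
  of cases is flagged prevalent for incident-filter testing. Designed
  proportion mediated for (T, CpG j, CHC) is the linear-probability
  closed form δⱼbⱼ/(Σδb + c), recorded in the ground truth.
* **Genotypes.** Dosages ~ Binomial(2, maf); optional correlated-SNP
  pairs (copy + resample) create LD blocks for pruning tests.

Default effect sizes are chosen for testability under the study
conditions of the validation experiments — δ = 0.8 M-units, M-noise sd
0.5, total logit-scale outcome path 1.0 — i.e. a strong but plausible
mediator CpG (standardized shift 1.6 sd) and a total-effect OR near e.
No array chemistry is simulated: no probe types, batch or chip effects,
no IDAT-level artifacts. Passing recovery tests therefore demonstrates
the statistical chain, not robustness to array technology.

## Validation experiments and problem sizes

The standing experiments (`ewasmed.experiments`, reported by
`scripts/acceptance.py` and asserted in the test suite) run at sizes that
keep one-core runtime in minutes:

* null calibration: 500 samples × 5,000 CpGs through the full
  simulate→QC→deconvolution→PCA→EWAS→genomic-control chain;
* power: 20 causal CpGs (δ = 0.8) among 2,000, n = 500;
* identity-link oracle: 20 random parameterizations, n = 300, 1,000
  draws, deviation measured in Monte-Carlo standard errors against
  â·b̂ fitted on the same data;
* designed-proportion recovery: 50 cohorts (n = 2,000, 100 CpGs, 1,000
  draws) cycling designs {0.10, 0.35, 0.55, 0.70}. Realized mean
  absolute error is ≈ 0.07–0.09 depending on seed: the per-cohort
  estimate carries a sampling sd of ≈ 0.07–0.09 at n = 2,000 simply from
  the logistic fit, so the experiment sits near its tolerance and larger
  cohorts (not larger draw counts) would be needed to tighten it;
* combined-score mediation on cohorts designed for 70%: averaged over 8
  replicates because one cohort's estimate has sd ≈ 8–9 points.

## Known limitations

* Sequential ignorability is assumed, not probed: no sensitivity
  analysis for unmeasured mediator–outcome confounding.
* CHCs are binary incident indicators; no time-to-event modelling.
* Residualizing on covariates *estimated from the methylation matrix
  itself* (cell proportions, PCs) slightly attenuates mediator signal at
  small CpG counts; at array scale the effect is negligible.
* The phi-based exclusion rule is a pragmatic collinearity guard, not a
  causal identification strategy; strongly co-occurring treatments remain
  mutually confounded by design.
* Probe-level exclusions (cross-reactive probes, SNP-proximal probes,
  sex chromosomes) are delegated to a user-supplied exclusion list; no
  list ships with the package.
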