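# Methods

This document records the exact conventions, estimators and defaults
implemented in `kernsurv`, including choices that are deliberate
approximations and their known limitations.

## 1. Profiles and preprocessing

An omic profile is a subjects×biomarkers numeric matrix
(`OmicMatrix`), of kind `continuous` (expression, methylation, copy
number, miRNA) or `binary` (somatic mutation indicators; validated to
contain only 0/1).

* **Missingness** (`impute_and_filter`): biomarkers with a missing
  fraction strictly above 20% (configurable) are removed; remaining
  missing cells are set to the biomarker's observed mean.  An optional
  expression filter removes biomarkers whose median is ≤ 0, intended
  for median-normalized log expression.
* **Standardization** (`standardize_profile`): continuous profiles are
  column-standardized to mean 0 and *population* variance 1 (divide by
  n), so that the linear kernel of a standardized profile has unit mean
  diagonal.  Zero-variance columns are dropped.  Binary profiles are
  never centered or scaled; their kernel diagonal is the normalized
  per-subject mutation burden.
* **Training/validation discipline**: standardization statistics
  (`StandardizationStats`) are estimated on training subjects only and
  applied unchanged to validation subjects; validation cells that are
  missing after transformation fall back to 0, the training mean on the
  standardized scale.  `align_subjects` restricts tables to their
  common subjects in a shared order.

## 2. Kernels and alignment

The similarity of two subjects within profile *m* is the
biomarker-averaged inner product

&nbsp;&nbsp;&nbsp;&nbsp;`K_m = Z_m Z_mᵀ / p_m`.

Kernel fusion is the nonnegative weighted sum `K = Σ_m σ²_m K_m`.

**Alignment** of two same-size matrices is the cosine of the Frobenius
inner product over all n² entries, diagonal included:

&nbsp;&nbsp;&nbsp;&nbsp;`A(K₁,K₂) = ⟨K₁,K₂⟩ / √(⟨K₁,K₁⟩⟨K₂,K₂⟩) ∈ [−1, 1]`.

Identities: `A(K,K)=1`, `A(K,−K)=−1`, `A=0` for matrices with disjoint
supports.  Applied twice the statistic yields a hierarchy: a
*profile-alignment matrix* (pairwise alignment of a cohort's kernels)
and a *cohort-alignment matrix* (alignment of vectorized
profile-alignment matrices, restricted to the profiles shared by all
cohorts).

## 3. Kernel-fusion Cox model

Hazard: `λ_i(t) = λ₀(t) exp(η_i)`, `η = Xβ + g`, with prior
`g ~ N(0, Σ_m σ²_m K_m)`.  This is exactly the random-coefficient model
`g = Σ_m Z_m α_m`, `α_mj ~ i.i.d. N(0, σ²_m / p_m)` — the representer
property the test suite verifies against an explicitly parameterized
solver.

### Inner loop (fixed σ²)

The penalized partial likelihood `l_cox(Xβ+g) − ½ gᵀK̃⁻¹g` is maximized
by Newton iterations in the joint (β, g) vector with step halving.

* Ties are handled by the **Breslow** approximation.  Value, gradient
  and the exact n×n Hessian `−Σ_t d_t (diag(π_t) − π_t π_tᵀ)` are
  computed in O(n²) by prefix sums over the descending-time order; the
  computation is shift-invariant in η (the maximum is subtracted before
  exponentiation).
* `K̃ = K + δI` with jitter `δ = 1e−8 · mean(diag K)`; the inverse uses
  the eigendecomposition with eigenvalues floored at δ, which keeps
  rank-deficient kernels (p_m < n, duplicated subjects) well posed.
  With such kernels the reachable gradient norm at the optimum is
  limited by the ~1e8 condition number; the solver accepts a numerical
  optimum when step halving can no longer improve the objective.
* No intercept is estimated (the Cox partial likelihood absorbs it into
  the baseline); the design matrix is checked for full column rank.

### Outer loop (variance components)

σ² maximizes the Laplace approximation of the integrated partial
likelihood

&nbsp;&nbsp;&nbsp;&nbsp;`l(σ²) = PPL(β̂, ĝ) − ½ log det(I + K̃ W)`,

with `W = −∂²l_cox/∂η²` at the inner optimum.  The criterion is
optimized derivative-free (Powell) on log σ² inside the box
[1e−6, 1e3], with warm-started inner solves.  Estimates at the lower
bound are flagged `no_signal`.

**Known limitation.** The integrated-partial-likelihood maximum itself
is biased toward zero for σ² in realistic regimes.  In the packaged
simulation at n=300, p=500, true σ²=1, 30% censoring, the estimator's
sampling mean is ≈0.55–0.65 (0.62 over the packaged 25 replicates); Monte-Carlo EM targeting the exact
integrated partial likelihood and PQL-type working-model REML give
essentially the same numbers, so this is a property of the estimand at
this information level, not of the Laplace approximation or the
optimizer (both were verified separately: the Laplace criterion matches
brute-force integration on tiny problems, and grid searches confirm
Powell finds the criterion's maximum).  Rank-based predictive
performance is insensitive to the absolute σ² scale, because the BLUP
direction changes only slowly with σ²; C-index results are therefore
unaffected in practice.  At this information level the held-out 80/20
C-index itself averages only ≈0.59 across replicates — close to the
oracle ceiling of ≈0.72 attainable with the true prognostic score under
this generative law, discounted by the accuracy with which a
240-subject training set recovers a 500-biomarker score.

### Prediction

Best linear unbiased prediction extrapolates the training BLUPs:

&nbsp;&nbsp;&nbsp;&nbsp;`ĝ_V = K_VT (K_TT + δI)⁻¹ ĝ_T`,

with the cross-kernel `K_VT = Σ_m σ̂²_m Z_m^V (Z_m^T)ᵀ / p_m` built from
validation profiles transformed with the frozen training statistics.
The overall risk score is `η̂_V = X_V β̂ + ĝ_V`.  A zero cross-kernel
yields a zero prediction; a duplicated subject reproduces its training
BLUP.  The baseline hazard is never estimated — all outputs are
relative risk scores, which is what the concordance index consumes.

## 4. Evaluation

* **Concordance index** (Harrell): computed via lifelines (scores are
  negated because lifelines orients them as higher-is-longer-survival);
  risk ties count ½; an outcome without comparable pairs raises.
  A brute-force pair-enumeration oracle backs the implementation in the
  test suite.
* **Monte Carlo CV**: repeated random 80/20 splits; split *r* uses seed
  `base_seed + r`; all preprocessing is refit on each training split;
  validation splits without events or comparable pairs are skipped,
  and more than 20% skips is an error.
* **External validation**: biomarkers are intersected with the training
  set (≥50% overlap required per profile), the frozen training
  statistics are applied, and a single external C-index is returned
  with an intersection report.
* **Down-sampling**: subjects (or biomarkers) are repeatedly subsampled
  without replacement at a decreasing grid of sizes; each draw is
  evaluated by k-fold CV; per-size mean C-indices quantify how
  performance degrades with cohort or panel size.

## 5. Comparators

Plain Cox models (clinical covariates, signature scores, subtype
indicator columns) delegate to scikit-survival with Breslow ties;
standard errors come from the inverse observed information.  The
L1-penalized Cox signature uses the Coxnet path with the penalty chosen
by inner k-fold CV on held-out partial log-likelihood, then refit on
the full training split.  Gene-list (metagene) scores are unweighted
mean expression over the listed genes; PRS scores are weighted dosage
sums with per-SNP mean imputation and a missing-SNP guard.  All
comparators share a uniform fit(training)/score(validation) interface
with the kernel method.

## 6. Cross-cohort meta-analysis

C-indices of method *j* in cohort *i* follow the random-intercept LMM

&nbsp;&nbsp;&nbsp;&nbsp;`y_ij = x_ijᵀβ + δ_i + ε_ij`,
`δ_i ~ N(0, σ_b²)`, `ε_ij ~ N(0, σ_ε²)`.

Estimation is REML with β and σ_ε² profiled out, leaving a 1-D bounded
search over λ = σ_b²/σ_ε² (the one-way covariance inverts in closed
form per cohort).  On balanced designs the interior optimum coincides
with the ANOVA method-of-moments solution exactly; λ is truncated at 0
when the boundary fits at least as well.  The cohort-driven share of
variance is `S = σ_b²/(σ_b²+σ_ε²)`.  Wald tests use the normal
reference.  Contrast helpers cover clinical-vs-omic,
per-profile deviations (sum-to-zero effect coding; the last profile's
deviation and SE come from the corresponding linear contrast),
combination-vs-single and signatures-vs-kernel comparisons.

## 7. Synthetic data

`generate_cohort` draws data from exactly the model's assumed
structure: standardized continuous profiles (or Bernoulli mutation
profiles with per-gene rates log-uniform on [0.001, 0.1]), random
biomarker coefficients `α_mj ~ N(0, σ²_m/p_m)`, fixed effects, and
event times `T ~ Exp(λ₀ e^η)` with λ₀ = 0.1.  Censoring is an
independent exponential whose rate is solved numerically (bisection on
the expected censored fraction) to hit the target rate.
`generate_cindex_table` simulates balanced cohort×method C-index tables
from the random-intercept LMM, refusing parameters that clip more than
5% of values outside [0, 1].  Everything is reproducible from integer
seeds.

## 8. Problem sizes used in the checks

The packaged checks run at desk scale, chosen to finish in minutes
while leaving the tested properties identifiable: alignment identities
at n≈20; solver equivalences at n=60–80 (p=15 for the representer
check); null-calibration CV at n=200, p=300, 50 repeats;
variance-component recovery at n=300, p=500, 25 replicates;
heterogeneity recovery on balanced 14×7 tables over 50 simulations; and
the subject down-sampling trend on a 220-subject cohort over a
220/160/100/60 grid with 3 repetitions of five-fold CV.
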