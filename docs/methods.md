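# Methods

This note documents the statistical procedures implemented in `manyweakiv`,
the numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Model and estimators

The structural model is linear with additive errors:

    y_i = x_i'β + u_i ,   x_i = Π'z_i + v_i ,   E[z_i u_i] = 0,

with one continuous outcome, `l` continuous exposures and `J` instruments
(genotype dosages 0/1/2 or allele scores). Confounding makes `u` and `v`
correlated, so OLS is inconsistent for β. Every estimator in the package
minimises a GMM criterion `Q(β) = n ĝ(β)' W⁻¹ ĝ(β)` with
`ĝ(β) = (1/n) Σ z_i (y_i − x_i'β)`:

- **2SLS** fixes `W = Z'Z/n`, giving `β̂ = (X'P_Z X)⁻¹ X'P_Z y`. Efficient
  under homoskedasticity, biased toward OLS with many weak instruments.
- **Two-step GMM** builds the efficient weight
  `Ω̂(β̃) = (1/n) Σ z_i z_i' û_i²` at a preliminary estimate (2SLS by
  default) and solves the weighted moment equations once.
- **CUE** minimises with `Ω̂(β)` evaluated at the same β as the moments.
  It is efficient under heteroskedasticity and, unlike 2SLS/two-step GMM,
  remains consistent under many-weak-instrument asymptotics.
- **LIML** is the CUE under an imposed homoskedastic weight
  `σ̂²(β) Z'Z/n`; the criterion then reduces to the variance ratio
  `n·u'P_Z u / u'u`, minimised exactly by the smallest eigenvalue λ of the
  pencil `(W'P_Z W, W'M_Z W)` with `W = [y X]`. The k-class value
  `κ = 1 + λ` is reported as `liml_kappa`; κ = 1 when J = l, where all IV
  estimators coincide.

The intercept is handled by demeaning y, X and Z once on construction,
algebraically identical to carrying an explicit constant through both
stages. All estimators work from cached cross-moment matrices, so a full
family fit touches the n-length data a handful of times; this is what makes
the Monte Carlo engine affordable.

## Inference

Conventional (fixed-J) standard errors: homoskedastic sandwiches for
OLS/2SLS, the k-class form `σ̂² [X'(I − κM_Z)X]⁻¹` for LIML, the
efficient-GMM variance `(n Ĝ'Ω̂⁻¹Ĝ)⁻¹` for two-step GMM and CUE;
heteroskedasticity-robust variants behind `robust=True`. Wald tests refer
to χ² (equivalently standard normal for a scalar); no small-sample t
correction is applied, matching the estimators' large-n theory. 95%
intervals use ±1.96·se at the presentation layer.

Under many-instrument asymptotics (J growing with n) the conventional LIML
and CUE standard errors are downward biased. The package implements:

- **Bekker variance for LIML** (sandwich form): with `û` the LIML
  residuals, `α̂ = û'Pû/û'û`, `H = X'PX − α̂X'X`,
  `X̄ = X − û(û'X)/(û'û)` (the exposure purged of its component correlated
  with the structural error) and `σ̂² = û'û/n`,

      V = H⁻¹ [ σ̂²((1−α̂)² X̄'PX̄ + α̂² X̄'M X̄) ] H⁻¹ .

  Its probability limit is `σ²/Φ + (α/(1−α))(σ²σ_v² − σ_uv²)/Φ²` (scalar
  case, Φ the concentration per observation), i.e. the conventional
  variance plus a positive many-instrument term that vanishes as J/n → 0.

- **Newey–Windmeijer variance for the CUE**: `V = H⁻¹ (n D̂'Ω̂⁻¹D̂) H⁻¹`,
  where `H` is half the Hessian of the CUE objective at the optimum
  (central finite differences, relative step 1e-4) and
  `D̂ = Ĝ − [Ĉ_k Ω̂⁻¹ ĝ]_k` recentres the moment derivative
  `Ĉ_k = −(1/n) Σ x_ik û_i z_i z_i'` by its correlation with the moments.
  With strong instruments `D̂ → Ĝ` and `H → n Ĝ'Ω̂⁻¹Ĝ`, recovering the
  efficient-GMM variance. A non-positive-definite Hessian triggers a
  warning and a fall-back to the efficient-GMM variance, flagged on the
  result.

Both corrections are validated two ways: against dense-matrix loop oracles
at toy sizes, and by their operating characteristics in the Monte Carlo
designs below (Wald rejection frequencies restored to 0.04–0.05 where the
uncorrected tests reject at 0.08–0.48).

Diagnostics and tests: joint first-stage F and partial R² (single
exposure), sample concentration `J(F−1)`, the approximation
`E[F] ≈ μ²/J + 1`, Sargan (`n·R²` of residuals on Z, homoskedastic) and
Hansen J (CUE objective at the estimate, robust) overidentification tests
with df = J − l, and the Hausman exogeneity test with a negative variance
difference clamped to zero with a warning.

### Bias approximations

With concentration parameter `μ² = nΠ'Σ_z Π/σ_v²` (for J i.i.d. variants
with common coefficient π and genotype variance `σ_z² = 2·maf·(1−maf)`,
`μ² = nJπ²σ_z²/σ_v²`):

- 2SLS: `(σ_uv/σ_v²)(J−2)·E[1/χ²_J(μ²)]`, the exact inverse moment of a
  noncentral chi-square evaluated by its Poisson-mixture series. It is
  increasing in J at fixed μ² and requires J > 3 for validity (J = 3 warns,
  J < 3 and μ² = 0 raise). The common closed-form simplification
  `(J−2)/(μ²+J−2)` is slightly smaller; the exact moment is used because it
  reproduces the known design values to three decimals.
- LIML: `−(σ_uv/σ_v²)/μ²`, independent of J and of opposite sign.

`first_stage_diagnostics` evaluates these at plug-in values (first-stage
residual variance; covariance of first-stage and OLS residuals) unless the
true design values are supplied — the plug-in σ̂_uv is itself attenuated by
confounding and should be read as a rough diagnostic only.

## Allele scores

`unweighted_score` sums allele counts; `weighted_score` applies external
per-allele effects, taken as given (in-sample re-estimation would reinstate
the overfitting external weights avoid). Scores may be standardised to mean
zero and unit sample SD (n−1 denominator); IV estimates and Wald statistics
are invariant to this rescaling, and score-IV with in-sample first-stage
coefficients as weights reproduces full-instrument 2SLS exactly (both
identities are asserted in the test suite).

## Synthetic-data generator and Monte Carlo engine

The generator draws `z_ij ~ Binomial(2, maf)` i.i.d. (inverse-uniform
sampling against the cumulative genotype probabilities) and sets

    x_i = π_z Σ_j z_ij + w_i + ε_xi ,   y_i = β x_i + w_i + ε_yi ,

with the confounder `w` and noises i.i.d. standard normal, so
`σ_v² = σ_u² = 2` and `σ_uv = 1`. The three standard designs (n = 3000;
J = 9, 25, 100 with π_z = 0.10, 0.06, 0.03; MAF 0.3; β = 0) all share
`μ² = 56.70`, hence approximate E[F] of 7.30, 3.27, 1.57 — the same total
instrument strength spread over ever weaker variants. For a central
first-stage F the exact mean is `(1 + μ²/J)·(n−J−1)/(n−J−3)`.

`run_monte_carlo` spawns one RNG substream per replicate from the master
seed (aggregates are therefore independent of execution order), fits the
requested estimators per replicate — the CUE from the five standard starts
`{−2,−1,0,1,2}×` the two-step GMM estimate — and aggregates medians, IQRs
and Wald rejection frequencies per standard-error flavour. Medians and IQRs
are used deliberately: LIML and the CUE occasionally produce very large
outliers, which distort means but not quantiles, and no trimming is
applied. Per-replicate failures are counted per estimator, excluded from
aggregates, and flagged when they exceed 1% of replicates.

What the generator does **not** emulate about real genotype data: linkage
disequilibrium between variants (entries are independent), departures from
Hardy–Weinberg proportions, population stratification, genotyping error or
missingness, heterogeneous per-variant effect sizes (except in the
`alspac_like` fixture), gene–environment interaction, and non-normal or
heteroskedastic errors. Passing Monte Carlo checks therefore demonstrates
correctness of the estimators and the size of the corrected tests under the
stated design, not robustness to those real-data features. The heteroskedastic
case — where LIML becomes inconsistent but the CUE does not — is exercised
only at unit-test scale, not in the study designs.

## Numerical choices

- **Weight-matrix convention**: Ω̂ uses uncentered outer products
  `Σ z_i z_i' û_i²/n` (the same object as the two-step weight); a centered
  variant (subtracting ĝĝ') is available behind `centered=True`.
- **Singular Ω̂**: Moore–Penrose pseudo-inverse with relative cutoff 1e-10,
  flagged on the result. With identically zero residuals (y exactly linear
  in X) the CUE criterion is scale-invariant in the residual and flat in β;
  the objective is still returned (zero at the exact coefficient), but no
  minimiser can identify β from it.
- **CUE optimisation**: for l = 1, bounded derivative-free scalar
  minimisation (bracket ±10 around each start, xatol 1e-9); quasi-Newton
  (BFGS) for l > 1. Ties between starts within 1e-12 in the objective break
  toward the smallest ‖β̂‖ for determinism. If no start converges the best
  value found is returned with `converged=False` and a warning.
- **LIML** is computed by eigen-decomposition, never iterative search —
  exact and fast inside Monte Carlo loops; eigenvalues below −1e-8 raise a
  degeneracy error, tiny negative values are clamped to zero.
- **Residual variance** uses the 1/n convention throughout (large-n theory;
  the first-stage F keeps its classical n−J−1 denominator).
- **Degenerate inputs**: constant instrument columns, rank-deficient Z'Z or
  X'P_Z X, and n ≤ J are rejected with typed errors at construction/fit
  time rather than producing NaNs downstream.

## Problem sizes in the test suite

The full study runs 10,000 replicates per design (`scripts/acceptance.py`,
a few minutes on one CPU). The test suite asserts the same quantities at
2500/2500/2000 replicates for J = 9/25/100 — enough to compare medians and
rejection frequencies at three Monte Carlo standard errors while keeping
the whole suite desk-scale — and validates estimators and standard errors
against loop-based oracles at n ≤ 100, J ≤ 5, where naive dense-matrix
algebra is feasible.

## Known limitations

- Only continuous outcomes and exposures; no binary-outcome IV, Fuller or
  jackknife estimators, structural mean models, Anderson–Rubin confidence
  regions or weak-instrument-robust test inversion.
- The Newey–Windmeijer correction is implemented for the moment design used
  here (instruments × residual); covariate-adjusted IV (beyond the
  intercept) is out of scope.
- The corrected-SE implementations assume J < n and are derived under
  homoskedasticity (Bekker additionally under approximate normality);
  their finite-sample size in the study designs is 0.04–0.05, slightly
  conservative of nominal.
- Genotype files must already be 0/1/2 dosage tables; VCF/PLINK parsing,
  LD pruning and strand resolution are upstream concerns.
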