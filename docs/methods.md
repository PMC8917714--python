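# Methods

This note documents the statistical machinery in `gbb8`: the models, the
estimation algorithm, the conventions adopted where several are in
circulation, the synthetic-data generator and what it does and does not
emulate, and the numerical choices. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Factor models

For p = 8 items loading one-per-item on K = 4 first-order factors, three
structures are supported.

**One-factor.** Σ = λφλᵀ + Θ with λ the 8-vector of loadings, φ the factor
variance, Θ diagonal residual variances.

**Correlated four-factor.** Σ = Λ₁ΦΛ₁ᵀ + Θ with simple-structure Λ₁
(two items per factor) and free K×K factor covariance Φ.

**Second-order.** The factor covariance is structured as
B = λ₂φλ₂ᵀ + Ψ_d: the four first-order factors load (λ₂) on one general
factor with variance φ; Ψ_d holds the first-order disturbances. Means
follow μ = ν + Λ₁(τ + λ₂α) with item intercepts ν, first-order intercepts
τ and the general-factor mean α.

**Identification** is by marker variables: the first item of each factor
has its loading fixed at 1, the first first-order factor is the marker of
the general factor, and latent means are identified by fixing the
reference group (first label in sorted order) to α = 0, τ = 0. Degrees of
freedom are invariant to this choice; the optimum log-likelihood is
invariant to re-identification (verified in the tests by swapping
markers). Item intercepts are always estimated; since free intercepts
saturate the mean structure, single-group χ² and df equal those of a
covariance-only analysis (44 moments − 24/30/28 free parameters = 20, 14
and 16 df for the three structures).

## Estimation: casewise (full-information) maximum likelihood

Each respondent contributes the log-density of their *observed* items
under the row/column-subsetted implied moments, which handles
missing-completely-at-random and missing-at-random data without
imputation. Respondents are grouped by missingness pattern and each
pattern is reduced to (n, mean, scatter), so one likelihood evaluation
costs O(#patterns · p³) regardless of sample size; with complete data the
criterion is exactly the sufficient-statistics ML log-likelihood.

The likelihood is maximised by L-BFGS-B with **analytic gradients**:
per-pattern accumulators ∂ℓ/∂Σ = n/2 (Σ⁻¹WΣ⁻¹ − Σ⁻¹) and
∂ℓ/∂μ = nΣ⁻¹(m − μ) are chained through the loading structure in closed
form (e.g. ∂ℓ/∂Λ₁ = 2AΛ₁B + gκᵀ). Variances are optimised on the log
scale, which enforces positivity; an estimate below 10⁻⁶ is reported as a
Heywood (boundary) warning, not an error. Convergence uses a relative
objective change below 10⁻¹⁰ and a projected-gradient norm of 10⁻⁵, with
500 iterations maximum; starting values are deterministic (loadings 1,
residuals at half the observed item variance, disturbances and factor
variances 0.5, intercepts at the observed means). A non-positive-definite
implied covariance at an iterate returns a large objective value and the
line search backtracks.

Two reference fits anchor the fit statistics:

* **saturated** — per-group unstructured (μ, Σ). With complete data these
  are the sample moments; with incomplete data they are obtained by EM
  (conditional-moment E-step on pattern sufficient statistics) run to a
  relative log-likelihood change of 10⁻⁸. The tests verify EM against the
  closed-form factored-likelihood (regression) solution on a monotone
  missingness pattern.
* **baseline** — independence model (free means and variances, zero
  covariances). Its casewise likelihood factorises per variable, so the
  solution is closed-form: available-case means and n-denominator
  variances.

The model χ² is 2(ℓ_saturated − ℓ_model), clamped at zero. Standard
errors come from the observed information (numeric Hessian of the
analytic gradient, central differences).

Respondents missing all eight items carry no information and are dropped
with a logged count, mirroring how fully empty questionnaires are handled
in survey data.

## Fit indices

* CFI = 1 − max(χ²_m − df_m, 0) / max(χ²_b − df_b, χ²_m − df_m, 0)
* TLI = ((χ²_b/df_b) − (χ²_m/df_m)) / ((χ²_b/df_b) − 1), clamped to [0, 1]
* RMSEA = √(G · max(χ² − df, 0) / (df · N)) with G groups and N the total
  sample size (N, not N−1 — the most common modern convention)
* SRMR = root of the size-weighted mean over groups of the mean squared
  correlation-metric residual over the p(p+1)/2 unique covariance
  elements; mean residuals are excluded (the dominant reporting
  convention).

Qualitative labels use the familiar two-tier cutoffs (CFI/TLI > .95 / .97,
RMSEA < .08 / .05, SRMR < .10 / .05 for acceptable/good). The χ² p-value
is reported but never used alone to reject a model. Robust (scaled) χ²
and index variants are out of scope; all output is labelled as plain
normal-theory ML.

## Reliability

Subscale ω uses the congeneric formula (Σλ)²/((Σλ)² + Σθ) with
unstandardized parameters; for subscales inside the second-order model the
item loadings are rescaled by the first-order factor's total SD so that ω
refers to the composite of observed items. For the second-order model the
two-level decomposition is

* ω_L1 = (1ᵀb)²φ / (1ᵀΣ̂1), b = Λ₁λ₂ — the share of the unit-weighted
  item-total variance explained by the general factor;
* ω_L2 = (1ᵀλ₂)²φ / ((1ᵀλ₂)²φ + 1ᵀΨ_d1) — the reliability of the
  first-order-factor composite.

ω_L2 ≥ ω_L1 whenever items carry residual variance. (Published reports of
this decomposition sometimes label both levels "ω_L1" — a typographical
slip; the two quantities are distinct and labelled distinctly here.)

## Measurement invariance

The eight levels add constraints cumulatively (G groups, reference group
first): configural (same pattern, all parameters group-specific, α = 0
everywhere); first-order weak (Λ₁ equal); second-order weak (+λ₂ equal);
first-order strong (+ν equal, τ freed in non-reference groups);
second-order strong (+τ equal at 0, α freed in non-reference groups);
first-order strict (+Θ equal); second-order strict (+Ψ_d equal); mean
equivalence (+α equal). Freeing τ at the first-order-strong step and α at
the second-order-strong step is standard practice and the only choice
consistent with the usual published df sequences (32, 36, 39, 43, 46, 54,
58, 59 for two groups; configural df 16G in general). Factor variances
remain group-specific throughout.

Each step is warm-started from the previous solution (tests confirm cold
starts reach the same optimum). A step passes when ΔCFI < .010 **and**
ΔRMSEA < .015, strict inequalities; Δχ² p-values are reported alongside
but do not decide. The overall verdict is the deepest consecutively
passing level.

A sensitivity asymmetry is worth knowing: with highly inter-correlated
items the baseline χ² is enormous, which makes CFI (and hence ΔCFI)
insensitive to localized misfit. An injected single-loading shift of 0.3
at n = 600/group moves ΔCFI by only ~.003–.005 but moves ΔRMSEA well past
.015, so the conjunction rule fails the step through its RMSEA arm. This
is a property of the indices, not of the implementation.

## Latent mean effect size

After strict second-order invariance, the mean-equivalence model is
compared to the strict model by likelihood ratio (Δdf = G − 1), and

f = √( Σᵢ nᵢ(αᵢ − ᾱ)² / n_total ) / ψ_P,  ᾱ = Σᵢ nᵢαᵢ / n_total.

ψ_P is implemented as √(Σᵢ nᵢ ψ²ᵢ / n_total) over the groups'
model-implied general-factor variances under the strict model — a
size-weighted pooling, the natural reading of "pooled across groups". For
two groups f reduces to |α₁ − α₂|√(n₁n₂)/(N·ψ_P) (an algebraic identity
the tests check over randomized inputs), and d = 2f, R² = f²/(1+f²)
follow Cohen's conventions.

## Descriptives conventions

SD uses n−1; skewness m₃/m₂^1.5 and kurtosis m₄/m₂² use n-denominator
central moments, and kurtosis is **raw** (normal = 3) — values near 1.7–2
for mildly platykurtic five-point items are only possible under the raw
convention. `r_subscale` is the correlation of an item with its subscale
partner (within a two-item subscale both items necessarily share the
value, the signature seen in published tables). `r_it` is uncorrected
(total includes the item); a corrected item-rest `r_ir` is emitted
alongside. Moments and correlations use pairwise deletion; Mahalanobis
screening uses complete cases, with flag threshold α = 0.001 by default
(a common choice where none is mandated) and flagged cases retained. The
identity ΣD² = (n−1)p holds exactly and is tested.

Pairwise deletion has one known consequence: the convergent-validity
correlation matrix is only approximately positive semi-definite under
missingness (exactly PSD on complete data); the observed perturbation at
2.5% MCAR is on the order of 10⁻³ in the smallest eigenvalue.

## Percentile-rank norms

PR(s) = round(100 · P(score ≤ s)), evaluated at every achievable score —
the cumulative-inclusive convention, under which norm columns are monotone
and the maximum attained score maps to 100. A mid-rank variant is
available behind a flag. Norms use scale-wise complete cases; no
imputation.

## The synthetic-data generator

The generator emulates the *design* of a GBB-8 validation study: two sex
groups of 333/304, age bands in proportions 239/182/96/121 of 638,
eight five-point items produced by thresholding Gaussian propensities
y* = λ₁f + √(1−λ₁²)ε at cut points (−0.85, −0.05, 0.65, 1.35), first-order
factors f = λ₂g + disturbance with unit variance in the reference group,
2.5% per-cell MCAR missingness, and standardized covariates r·g + noise at
target correlations (.68, .69, .79, .70) emulating the published
convergent-validity regime. Default loadings are λ₁ = 0.88 and λ₂ = 0.90:
categorisation at these thresholds attenuates observed correlations by a
factor a² ≈ 0.90 (a = Σφ(τ_k)/σ_cat), and λ₁ = 0.88 is what places the
observed partner correlations near .70 and subscale ω near .80–.86, the
published regime. Item means then sit near 1.6 and SDs near 1.2.

What the generator does **not** emulate: respondent heterogeneity beyond
the factor model (no response styles, acquiescence, careless responders),
non-ignorable missingness (MCAR only — FIML's ignorability assumption is
satisfied by construction), item-level covariate structure (covariates are
generated at the latent level since only sum-score correlations are
used), and real sampling artefacts of online panels. Passing calibration
tests therefore demonstrates correctness of the machinery under the
assumed model, not robustness to violations of it.

Determinism: one config (including seed) yields bit-identical integer
responses, labels and covariates.

## Monte-Carlo problem sizes

The packaged calibration suites use study-scaled designs chosen to keep
the default test run fast: 100 replicates of the full eight-step ladder on
fully invariant two-group data (n = 600/group, complete) for the null
pass rate (criterion ≥ 90%) and the mean-equivalence LRT type-I rate
(acceptance band = central ≈99% binomial region around 5% at 100
replicates); 15 replicates for the injected-loading-shift sensitivity
check (majority must fail the weak step); loading recovery at n = 20 000
(±0.05 on standardized loadings); latent-mean recovery at n = 4000/group
(±0.05 on the standardized offset, ±0.1 on d). `scripts/acceptance.py`
re-runs the same designs with seeds derived from `--seed`.

## Known limitations

* Likert items are treated as continuous: latent standardized loadings are
  recovered only up to the categorisation attenuation (~4% downward at
  the default thresholds) — within the ±0.05 recovery band, but a real
  bias. Polychoric/ordinal estimation would remove it and is out of scope.
* Plain ML only: no scaled/robust χ² or indices, no standard-error
  corrections for non-normality beyond what FIML provides.
* No partial-invariance search, modification indices, or alignment
  estimation; a failed ladder step reports, it does not localise.
* RMSEA/CFI conventions vary across software (N vs N−1, group
  multiplier); comparisons with other implementations should check
  conventions before comparing third decimals.
* The baseline-χ²-driven insensitivity of ΔCFI documented above means
  ΔCFI-only decision rules would under-detect loading non-invariance in
  highly homogeneous instruments; the conjunction with ΔRMSEA mitigates
  this.
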