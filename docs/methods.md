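# Methods

## The model

`cfams` studies confirmatory factor analysis (CFA) with and without a mean
structure. The covariance model for p observed variables x is

    x = τ + Λξ + δ,    Σ = ΛΦΛ′ + Θδ,    μ = τ + Λκ,

with Λ the p×q loading matrix (simple structure throughout), Φ the factor
covariance matrix, Θδ the diagonal matrix of unique variances, τ the item
intercepts and κ the factor means. Covariance-only CFA estimates θ =
(Λ, Φ, Θδ) from the sample covariance S; the mean-and-covariance model
(CFA-MS) adds ν = (τ, κ) and fits (S, x̄) jointly. The scientific question is
how much the mean structure helps the estimation of *weak* loadings — here,
loadings of 0.30.

## Population models and design

Three generating models with p = 12 standardized indicators:

| model | loadings by factor | intercepts τ | means κ |
|-------|--------------------|--------------|---------|
| 1F | 0.30 ×12 | 3 ×12 | 6 |
| 2F | 0.80 ×7, 0.30 ×5 | 8 ×7, 3 ×5 | 12, 6 |
| 3F | 0.95 ×5, 0.70 ×4, 0.30 ×3 | 9.5 ×5, 7 ×4, 3 ×3 | 12, 8, 6 |

Unique variances are θδ,ii = 1 − (ΛΦΛ′)ii so all observed variances are 1;
the loading values are then both raw and standardized population loadings.
Factor correlations are 0 or 0.50, applied to every factor pair.

The experimental factors are estimation method (ML, ULS), sample size
N ∈ {100, 300, 500}, factor correlation (except 1F), and the mean-structure
constraint:

* **NONE** — covariance-only CFA.
* **C1** — saturated mean structure: one marker loading per factor fixed at
  1 and its intercept at 0; all remaining intercepts and all κ free.
* **C2** — tau-equivalent: every τ fixed at 0, κ free.
* **C3…C5** — the intercepts of one factor's items (plus each factor's
  marker) fixed at 0, the others free; the last constraint of each
  multi-factor model zeroes the weak factor's intercepts. In 1F, C3 fixes
  every other intercept.

This crossing yields 24 + 60 + 72 = 156 design cells; at the full scale of
1000 replications per cell it amounts to 156,000 estimations.

## Identification

Two equivalent identifications are supported: unit factor variances
(diag(Φ) = 1, all pattern loadings free) and marker scaling (one loading per
factor fixed at 1, factor variances free — the form in which the saturated
constraint C1 is usually stated). They parameterize the same model manifold
and give identical fitted moments and standardized solutions. Fitting always
uses the unit-variance coordinates: the marker metric has a degenerate ridge
(factor variance → 0 with loadings diverging) precisely when the marker
loading is weak, and optimizing there sent a quarter of the saturated-C1
fits of the one-factor model into that ridge. The marker coordinates remain
available for the efficiency calculus and for reparameterization checks.
Reported loadings are always rescaled to the unit-observed-variance
metric, λ_std = λ̂ √φ̂jj / √σ̂ii with σ̂ii the implied item variance, which
makes the two identifications comparable; each factor is also reflected, if
necessary, so the sum of its pattern loadings is nonnegative (the covariance
structure is invariant under reflection, and without alignment a reflected
weak factor would register as a recovery failure that is purely notational).

## Estimation

ML minimizes F = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p, plus
(x̄−μ)′Σ(θ)⁻¹(x̄−μ) when means are modeled. ULS minimizes ½ tr[(S−Σ)²],
plus ½|x̄−μ|² when means are modeled; the identity weight and the ½ make the
mean term symmetric with the covariance term.

The optimizer is damped Fisher scoring: Newton steps with the expected
(information-matrix) Hessian — 2Ic + 2J′Σ⁻¹J for ML, the Gauss–Newton
surrogate for ULS — a Levenberg ridge when the solve fails or the step is
not a descent direction, and an Armijo step-halving line search. Gradients
are analytic. Generic limited-memory quasi-Newton methods were tried first
and could not traverse the ill-conditioned mean-structure problems (the free
parameters span scales from 0.3 loadings to factor means near 16) within any
reasonable iteration budget; expected-information steps are the standard
cure in structural equation modeling and are what the classical SEM programs
use.

* Iteration cap: 250. Convergence: relative decrease of F below 1e-6, or a
  vanishing gradient. Hitting the cap or a stalled line search flags the fit
  non-convergent; the result is retained but excluded from summaries.
* Start values are structure-agnostic: loadings 0.5, unique variances 0.5,
  factor covariances 0 (variances 0.5 when free). The mean side starts
  feasible: κ at the least-squares solution of the fixed-intercept items'
  mean equations and the free τ absorbing the remaining sample means. A cold
  κ = 0 start leaves an initial mean misfit of order |x̄|² that dominates
  the discrepancy and reliably drags the loadings into poor local optima.
* Unique variances are not bounded, so Heywood cases are observable:
  a convergent fit with any θ̂δ,ii ≤ 0 is flagged and deleted from cell
  summaries. A fit whose standardized solution is non-finite (possible only
  under C1's free factor variances going negative) is put in the same
  improper bucket, so valid + non-convergent + improper = replications.

## Recovery and efficiency metrics

**RMSD** per factor k: √( Σi (λik(t) − λik(e))² / p_k ) over the p_k items
defining the factor, on standardized loadings; 0 is a perfect match, 2 the
all-ones-vs-all-minus-ones extreme, and values below 0.20 count as
satisfactory. The study's dependent variable is the weak factor's RMSD.

**Information calculus.** With Ic the covariance-structure information
(Ic,jk = ½ tr(Σ⁻¹ ∂Σj Σ⁻¹ ∂Σk) on free coordinates), the mean structure
adds (κκ′)⊗Σ⁻¹ on the loading block and couples to ν through
J′Σ⁻¹J blocks. The net information about θ is the Schur complement
I*θθ − Iθν Iνν⁻¹ Iνθ — positive semi-definite, zero exactly when the mean
structure is saturated (free ν count = p) or κ = 0. Asymptotic covariances
are Vθθ = Ic⁻¹ and Vθθ* = (Ic + net)⁻¹. Constraints are handled by reducing
every block to the free coordinates; under C1 the true parameters are first
mapped into the marker metric (λ* = λ/λ_m, φ*jk = λ_mj λ_mk φjk, κ*_j =
μ_mj/λ*_mj, τ* = μ − Λ*κ*).

**ARE** of a loading estimate is Var(√n λ̂)_CFA-MS / Var(√n λ̂)_CFA.
The analytic version takes the diagonals of Vθθ* and Vθθ on loading
coordinates. The replication engine uses the empirical version: the ratio of
across-replicate variances of the weak factor's standardized loadings,
mean-structure cell over the covariance-only cell of the same
(model, N, method, correlation) slice. Both cells consume the identical
simulated samples (seeds are a deterministic function of master seed, model,
correlation, N and replicate index, shared across methods and constraints),
and only replicates valid in both fits enter, paired. ULS cells use the
same empirical definition even though the information calculus is
ML-specific. Cell-level ARE is the mean over the weak factor's loadings.

## Data generation

Samples are drawn from MVN(μ, Σ) at the population moments; latent variables
are never materialized (distributionally equivalent under the linear model).
S uses the N−1 divisor. The generator emulates multivariate-normal sampling
only — no non-normality, missingness, or model error — so passing tests
speak to the estimators' behavior under a correctly specified normal model,
not to robustness on real data.

## The ANOVA metamodel

Per-replicate weak-factor RMSD (and per-loading ARE) are decomposed by a
factorial model with main effects M, N, C, CO and all two-way interactions
(CO terms absent for 1F). Sums of squares are Type II — exact under balance
and stable under the mild unbalance left by deleting improper solutions;
cells emptied entirely are dropped with a warning. The effect size reported
as η² is the partial form SS_effect/(SS_effect + SS_error); that is the
form consistent with the published decompositions this package mirrors,
where the per-effect values are accompanied by a total explained variance
(here the model R²) that is much smaller than their sum. The classical
SS_effect/SS_total is reported alongside. Interpretation bands: below 0.05
negligible, 0.05–0.09 small, 0.10–0.20 medium, above 0.20 large. The ARE
ANOVA takes per-loading ARE values as observations (item-level), matching
the small error degrees of freedom of the published tables.

## Problem sizes and numerical choices

The default study scale is 100 replications per cell (the full 156-cell
screen, 15,600 fits, a few minutes on one CPU); the metamodel runs use 200
replications per cell per model; 1000 per cell mirrors the full design.
Monte Carlo information checks use 800 replications at N = 2000.
Comparisons against published rates use three binomial Monte Carlo standard
errors; η² comparisons use a 0.10 absolute band. The master seed defaults
to 20160105; all per-replicate seeds derive from it via SeedSequence.
Degenerate inputs (non-positive-definite S, N ≤ p) are rejected or flagged,
never silently accepted; a non-PD implied Σ during optimization returns a
penalty value and the line search backtracks.

## Known limitations

* The original study's covariance-only cells show weak-factor RMSD around
  0.21–0.30 that barely improves with N. A correctly specified ML/ULS
  estimate of this model cannot behave that way: the Fisher information
  gives per-loading asymptotic variances of about 1.8/N for the 1F model
  (≈ 0.14 RMSD at N = 100), and this package's estimates match that theory
  (and their own Monte Carlo variances) to within a few percent. The
  published covariance-only levels therefore appear to carry a component of
  the original optimizer's behavior on these deliberately weak, flat
  likelihoods (limited iterations from instrumental-variable starts) rather
  than a property of the estimand. Consequences: covariance-only RMSD cells
  here are systematically lower than the published ones, the RMSD η² for
  constraints comes out smaller and for sample size larger, and the
  non-convergence rate is far below the published 9.2% (Fisher scoring with
  analytic gradients converges almost everywhere the published workflow did
  not). The mean-structure cells, Heywood rates, proper-solution ordering
  1F > 2F > 3F, and the ARE decompositions reproduce well.
* Empirical ARE for the saturated C1 pattern can fall below 1 even though
  the net-information theory predicts exactly 1: the theory compares fixed
  parameterizations, while the empirical ratio compares standardized
  loadings across differently identified fits. The analytic calculator
  returns 1 for C1.
* No robust/sandwich standard errors, missing data, multiple groups,
  cross-loadings beyond the simple-structure patterns, or non-normal data.
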