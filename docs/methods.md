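# Methods

This note documents the statistical models implemented in `stoplatent`,
the defaults of the synthetic-data generator, and the numerical and design
choices a user should know before trusting (or extending) the results.

## Latent class analysis

The phenotype model is a finite mixture for J binary items: subject i
belongs to class k with probability π_k and endorses item j with
probability ρ_kj, items conditionally independent given class. The
observed-data log-likelihood is maximized by EM. Two implementation points
matter in practice:

* **Pattern collapsing.** The E/M steps operate on unique response
  patterns with multiplicities, not on subjects. With 22 binary items and
  well-separated classes the number of distinct patterns is orders of
  magnitude below n, which is what makes enumeration over K plus a
  parametric bootstrap affordable at cohort sample sizes.
* **Starts and convergence.** ρ starts are Uniform(0.1, 0.9), π starts
  Dirichlet(1); 50 starts for enumeration and 20 inside bootstrap refits
  (both configurable). Convergence is a relative log-likelihood change
  below 1e-6 (cap 500 iterations); the EM ascent property is asserted at
  every iteration. ρ estimates are clamped to [1e-4, 1 − 1e-4] to keep the
  boundary likelihood finite. A solution counts as "replicated" when at
  least two starts reach the best log-likelihood within 1e-3.

Enumeration reports AIC = −2LL + 2p, BIC = −2LL + p·ln n,
ABIC = −2LL + p·ln((n+2)/24) with p = (K−1) + K·J, relative entropy
(defined 1 for K = 1), and three likelihood-ratio tests. The VLMR/LMR pair
uses a chi-square reference with df equal to the parameter-count
difference, and the LMR-adjusted statistic divides the LR by
1 + 1/(df·ln n); both are approximations to the exact weighted-chi-square
reference and are labeled approximate. Because mixture LR statistics under
the null tend to be stochastically smaller than that chi-square, the
approximation errs conservative. The parametric bootstrap is the
authoritative test: B datasets from the (K−1)-class MLE, both models
refitted per dataset, p = (1 + #{boot ≥ obs})/(B + 1), so the attainable
minimum is 1/(B+1) and rejection decisions should use p ≤ α.

Selection applies five criteria per K (information criteria all decreased,
entropy > 0.90, all available LRT p < .05, smallest class > 2%, best
log-likelihood replicated) and picks the largest passing K whose successor
fails at least one; if the top of the fitted range passes everything the
report says so rather than extrapolating.

Standard errors via robust (sandwich) ML scaling are *not* implemented for
the LCA parameters; no reported quantity requires them.

## Coactivation networks

### EFA and the discard screen

Exploratory extraction is maximum likelihood on the correlation matrix
(delegated to statsmodels), with oblique geomin rotation (ε = 0.01,
gradient-projection algorithm, 10 random orthonormal starts) for ≥ 2
factors. The screen discards a candidate structure when the r-th
eigenvalue of the sample correlation matrix is < 1, when two or more
indicators cross-load above 0.10 in absolute value, or when any factor
retains ≤ 2 indicators; indicators whose primary loading is below 0.30 are
dropped and the structure re-fitted before the verdict. Among admissible
candidates the most granular (largest factor count) is retained.

### CFA

The confirmatory model per group g is

    η = α_g + Γ x + ζ,  ζ ~ N(0, Ψ_g)
    y = ν_g + Λ_g η + ε, ε ~ N(0, diag(θ_g))

with simple structure (each indicator loads on one factor). Identification
fixes the first loading of each factor at 1 with the factor variance free;
single-group latent means are 0. Covariates enter as exogenous predictors
of the factors (MIMIC); the covariate block is handled by fitting the
joint (y, x) moment structure with a saturated x block, which leaves the
discrepancy and degrees of freedom identical to the conditional
formulation. Estimation minimizes the ML discrepancy
F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p + (m̄−μ)'Σ⁻¹(m̄−μ), summed over groups
with weights n_g/N, by L-BFGS-B with numerical gradients; positive
definiteness is enforced through Cholesky factorization (a determinant
sign test is not sufficient), Ψ is parameterized by a log-diagonal
Cholesky factor, and θ is left unconstrained so Heywood (negative
uniqueness) solutions are representable and flagged rather than hidden.
When the quasi-Newton pass fails or terminates at a large discrepancy
(F > 0.5 — near-singular samples put the optimum in a narrow curved
valley), a Nelder-Mead polish plus a second L-BFGS pass is run and the
best of the three results kept.

Model χ² is N·F_min. Fit indices: CFI and TLI with the independence
baseline (diagonal indicator covariance, free means, saturated covariate
block, zero indicator-covariate covariance), RMSEA =
√(G·max(χ²−df, 0)/(df·N)) with the number-of-groups multiplier and a 90%
CI from noncentral-χ² inversion, and SRMR as the RMS standardized
covariance residual pooled across groups (covariance part only). The
robust-ML (MLR) χ² scaling correction is not implemented anywhere; all
indices use the standard ML χ².

Binary symptom scales use a two-stage estimator: pairwise tetrachoric
correlations (bivariate-normal ML with thresholds fixed at the item
margins; empty 2×2 cells get a +0.5 continuity correction and a flag)
followed by unweighted least squares on the off-diagonal correlations.
The reported χ² = (N−1)·F_ULS is an approximation (no weight-matrix
correction) and is labeled as such; a full WLSMV estimator is out of
scope.

## Measurement invariance and latent contrasts

The ladder fits configural (all measurement parameters group-specific,
latent means fixed at 0), metric (loadings equated), and scalar (loadings
and intercepts equated, latent means free except the reference group)
bottom-up. A step is rejected only when ΔCFI > 0.01 **and** ΔRMSEA > 0.015
— the conjunctive rule; one criterion alone does not reject. When scalar
invariance fails no partial-invariance fallback is attempted (an explicit
override flag exists for diagnostics). Covariate effects Γ are
group-specific in the configural model and equated from metric upwards.

Latent contrasts are all pairwise α differences per factor, with SEs by the
delta method from the observed-information covariance of the free
parameters (numerical Hessian of the total log-likelihood), Wald z tests,
and BH-FDR within each factor's family of 6 pairwise contrasts. Cohen's d
is defined here as |Δ| divided by the pooled model-implied latent SD
(group-size-weighted); this is a documented convention — published d values
for such contrasts are generally not recoverable from printed estimates
and SEs, and no attempt is made to reproduce them. The family-clustering
option replaces the covariance with a cluster-sandwich form
A⁻¹(Σ_c s_c s_c')A⁻¹ using cluster-summed casewise scores (numerical
central differences); point estimates are unchanged and clusters may span
groups.

## SST behavior and QC

Integration-method SSRT: p(respond|signal) counts every stop-trial
response including premature ones; go omissions are assigned the maximum
observed go RT; the index into the ascending adjusted go-RT list is
⌈p·N_go⌉ (ceiling convention, following consensus-guideline practice;
the rounding rule is otherwise arbitrary); SSRT = nth go RT − mean SSD
over all stop trials. p = 0 returns a flagged missing result. The estimate
is invariant to trial ordering.

Exclusions: mean framewise displacement ≥ 0.9 mm (inclusive), total
degrees of freedom ≤ 200, FreeSurfer QC fail, SST performance flag fail
(consumed as a provided boolean), any response < 50 ms on a stop trial
with SSD = 50 ms, and ≥ 10% of stop trials at SSD = 0 ms. Every exclusion
carries its triggering rules; missing required fields exclude with an
explicit "missing" reason.

Winsorization is conditional and single-pass: a region is flagged only
when at least one value lies outside mean ± 3 SD **and** the absolute
adjusted Fisher-Pearson moment skewness exceeds 2; out-of-bound points are
clipped to the boundary computed from the original column (no iterative
recomputation). Note that a lone extreme point inflates its own column SD,
so very short columns cannot trigger the rule — a single outlier can only
exceed 3 SD when n ≥ 11. Zero-variance columns are skipped and noted.

## Region-level mixed models

The model is y = Xβ + u_site + e, u_site ~ N(0, σ_s²), estimated by REML
with the variance ratio γ = σ_s²/σ_e² profiled out; the scalar criterion
log|V| + log|X'V⁻¹X| + (n−p)·log(r'V⁻¹r) is minimized by bounded search on
log γ with an explicit γ = 0 boundary check, using per-site Woodbury
identities so cost is linear in n. The omnibus group test is a Wald F with
a Satterthwaite-style denominator df: per-eigencomponent Satterthwaite df
(gradient of the contrast variance with respect to (σ_e², σ_s²) against
the inverse REML Hessian) combined by the standard
ddf = 2E/(E−q), E = Σ ν_i/(ν_i−2) rule; degenerate cases fall back to the
residual df. η² is the semi-partial SS_group/SS_total computed on the
GLS-whitened scale. Categorical covariates are dummy-coded against the
modal level; singular designs raise an error naming the aliased columns.
With fewer than two sites the model falls back to OLS with a warning; one
subject per site makes GLS and OLS coincide exactly. Crossed random
effects (site × family simultaneously) are not supported; family
clustering is available through the latent-contrast sandwich option.

## The synthetic-data generator

The generator defines the study conditions used throughout the tests:

* **Symptoms.** Four classes with mixing proportions 9781/787/901/279 of
  11,748 (prints as 83.3/6.7/7.7/2.4%). Endorsement profiles are a
  synthetic calibration of the published class profiles, which are
  reported only graphically: the low/typically-developing profile at 0.02,
  high blocks at 0.90, the moderate-ADHD block at 0.50, with co-occurring
  irritability at 0.20 and mild elevations (0.05-0.06) elsewhere. These
  class separations are deliberately clean; real K-SADS data are noisier,
  so recovery rates measured here are upper bounds.
* **Betas.** Indicator i of factor block f is
  λ_i(α_g + γ'x + ζ_f) + u_{site,i} + ε_i with Var(ζ) = 1 and
  θ_i = 1 − λ_i², so the site/covariate-free implied indicator correlation
  is λ_iλ_j. Default loadings: response inhibition (0.91, 0.86, 0.68,
  0.51); error processing (0.84, 0.93, 0.79) and (0.93, 0.98, 0.68) with
  inter-factor correlation 0.4. Default response-inhibition latent means
  across classes: (0, 0.17, −0.17, −0.56); error-processing means 0 (the
  published group differences there were null). Site intercepts are drawn
  per (site, region) with SD 0.15 across 21 sites; covariate effects
  default to zero (no published generative values exist) and are injected
  explicitly by tests that need them.
* **SST sessions.** 2 runs × 180 trials with 30 stop trials per run; a
  one-up/one-down staircase with 50 ms steps starting at 50 ms (task
  convention; the step and start are not published quantities), floored at
  0 ms, persisting across runs; lognormal go RTs (median 500 ms, log-scale
  0.25); a 2% go-omission rate; an independent-race responder with true
  SSRT 280 ms (the observed mean SSRT in the study population is ≈ 262 ms;
  280 ms is a calibration choice inside that range, not a published
  generative value). Because the staircase starts well below its
  equilibrium, the pooled stop-success rate sits slightly above the 50%
  tracking target (the early trials are easy); this is a faithful
  consequence of the task design, not an estimator bias.
* **Covariates/QC.** Independent draws matched to the published sample
  description (age 9.9 ± 0.6 y, 52.9% female, etc.); sibling pairs share a
  family id at a configurable rate (default 10%). The generator does not
  emulate covariate-phenotype confounding, missing symptom data (available
  as an injection utility only), scanner-specific beta scaling, or any
  violation of the race model — so passing tests demonstrate correctness
  of the estimators under the assumed data model, not robustness to
  real-data pathologies.

## Problem sizes used in the checks

The bundled checks run at deliberately chosen sizes: class-share
convergence at n = 100,000; LCA enumeration with B = 50 bootstrap
replicates at n = 5,000 and proportion recovery at n = 10,000; CFA loading
recovery at n = 5,000; the invariance ladder's null/alternative behavior
at n = 2,000 per group over 100 replications; type-I-error calibration of
the mixed-model omnibus test and the bootstrap LRT over 200 null
replications (B = 19 inside the calibration loop); and an end-to-end
pipeline run at n = 1,200. At that pipeline size the rarest class (~2.4%,
≈ 29 subjects) is not always retained by the 2% selection floor — an
expected small-sample behavior; class-count recovery is assessed at
n = 5,000.

## Known limitations

* VLMR/LMR p-values are chi-square approximations, not the exact weighted
  reference; the parametric bootstrap should carry inferential weight.
* The binary-item CFA χ² is an undocumented-weight ULS approximation;
  its absolute fit indices should be read qualitatively.
* No MLR scaling, no ESEM/bifactor models, no mixture-SEM joint
  estimation (class labels enter downstream stages as fixed modal
  assignments — a two-stage procedure that understates posterior
  uncertainty when entropy is low; with the default well-separated
  classes entropy is high and the effect negligible).
* The Satterthwaite machinery covers a single random intercept; family
  and site nesting cannot be modeled simultaneously.
* η² in the regional tables is the semi-partial definition given above;
  it is not comparable to published tables that use other (sometimes
  inconsistent) definitions.
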