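# stoplatent

Latent phenotyping and latent neural-coactivation analysis for stop-signal
task (SST) cohort studies.

Large developmental cohorts ask a recurring question: do children with
different symptom profiles — for example high ADHD symptoms with
co-occurring irritability, moderate ADHD alone, or high irritability alone —
differ in the brain activity that supports response inhibition and error
processing? `stoplatent` implements the full analysis chain used to answer
it from tabular inputs (binary K-SADS-style symptom items, region-level
task-contrast beta weights, socio-demographic covariates, trial-level SST
event tables), together with a synthetic-data generator that reproduces the
statistical structure of such a cohort so every stage is testable without
restricted data.

## What it computes

**Latent class analysis (LCA).** Subjects belong to an unobserved class
k ∈ {1..K} with probability π_k and endorse binary item j with
class-conditional probability ρ_kj. Estimation is multi-start EM over
unique response patterns; class enumeration reports AIC, BIC,
sample-size-adjusted BIC (−2LL + p·ln((n+2)/24)), relative entropy
E = 1 − Σᵢₖ(−p_ik ln p_ik)/(n ln K), VLMR/LMR-adjusted LRTs (chi-square
approximations, labeled approximate), and the parametric bootstrapped LRT
with p = (1 + #{boot ≥ obs})/(B + 1). A model is selected when it passes all
criteria — decreasing information criteria, entropy > 0.90, all LRT p < .05,
class proportions > 2%, best log-likelihood replicated — and its successor
fails at least one.

**Coactivation networks (EFA → CFA).** Region-level betas are modeled as
indicators of latent factors: y = ν + Λη + ε with η = α_g + Γx + ζ,
ζ ~ N(0, Ψ), ε ~ N(0, diag(θ)). Exploratory structures (ML extraction,
oblique geomin rotation) are screened by the standard discard criteria
(eigenvalues < 1, cross-loadings > .10, primary loadings < .30, factors with
≤ 2 indicators); the survivor is confirmed by ML CFA with
χ² = N·F_ML, CFI, TLI, RMSEA (with 90% CI by noncentral-χ² inversion) and
SRMR. Binary symptom scales use a tetrachoric + ULS two-stage fit.

**Measurement invariance and latent contrasts.** The multi-group ladder
(configural → metric → scalar) rejects a step only when ΔCFI > .01 **and**
ΔRMSEA > .015. Under the scalar model, group differences are latent-
intercept contrasts α_g₂ − α_g₁ (reference fixed at 0) with delta-method
SEs, Wald z tests, Benjamini–Hochberg FDR within each factor's contrast
family, and Cohen's d = |Δ|/pooled model-implied latent SD. A cluster-robust
(sandwich) covariance replaces the observed-information covariance when
subjects are nested in families.

**SST behavior and QC.** Integration-method SSRT (omissions replaced by the
maximum observed go RT, premature stop responses counted as failed stops,
n = ⌈p·N_go⌉, SSRT = nth go RT − mean SSD); exclusion rules (mean FD ≥ 0.9
mm, dof ≤ 200, FreeSurfer QC fail, performance flag, speedy responses at
SSD = 50 ms, ≥ 10% stop trials at SSD = 0 ms); conditional winsorization of
betas (clip to mean ± 3 SD only when a point is out of bounds **and**
|skewness| > 2).

**Region-level mixed models.** y = Xβ + u_site + e with profiled-REML
estimation of the site variance ratio, Wald omnibus F with Satterthwaite-
style denominator df, semi-partial η², BH-FDR across regions, and optional
sex × group interaction scans.

## Worked example

```python
import numpy as np, pandas as pd
from stoplatent import (PhenotypeGenConfig, NeuroGenConfig, generate_symptoms,
                        generate_betas, LatentClassModel, FactorModelSpec,
                        fit_cfa, fit_indices, fit_multigroup,
                        compare_latent_means)
from stoplatent.simulate import _default_ri_blocks

# 1. synthetic cohort: recover the four phenotype classes
pheno = PhenotypeGenConfig(seed=0)
symptoms, true_class = generate_symptoms(pheno, n=10_000)
lca = LatentClassModel(n_classes=4, n_starts=50, random_state=0)
lca.fit(symptoms.drop(columns="subject_id"))
print("class proportions:", np.sort(lca.weights_)[::-1].round(3))

# 2. response-inhibition network: confirm loadings, compare latent means
blocks = _default_ri_blocks()
neuro = NeuroGenConfig(factor_blocks=blocks, site_sd=0.0, seed=0,
                       group_latent_means=np.array([[0.0], [0.17],
                                                    [-0.17], [-0.56]]))
betas = generate_betas(neuro, true_class)
spec = FactorModelSpec(factors={"ri": blocks[0].indicators})
fit = fit_cfa(spec, betas)
print("standardized loadings:",
      fit.standardized_loadings().round(2).T.values.ravel())
idx = fit_indices(fit)
print(f"CFI={idx.cfi:.3f} RMSEA={idx.rmsea:.3f} SRMR={idx.srmr:.3f}")

groups = pd.Categorical(
    pd.Series(true_class).map({0: "td", 1: "adhd_irr", 2: "adhd", 3: "irr"}),
    categories=["td", "adhd_irr", "adhd", "irr"])
scalar = fit_multigroup(spec, betas, groups=groups, level="scalar")
print(compare_latent_means(scalar)[
    ["group_1", "group_2", "estimate", "se", "p_fdr"]
].round(3).to_string(index=False))
```

Output:

```
class proportions: [0.834 0.074 0.067 0.024]
standardized loadings: [0.91 0.86 0.68 0.51]
CFI=1.000 RMSEA=0.000 SRMR=0.001
 group_1  group_2  estimate    se  p_fdr
      td adhd_irr     0.147 0.039  0.000
      td     adhd    -0.121 0.037  0.001
      td      irr    -0.551 0.064  0.000
adhd_irr     adhd    -0.268 0.052  0.000
adhd_irr      irr    -0.698 0.074  0.000
    adhd      irr    -0.430 0.072  0.000
```

The recovered class shares match the generator's mixing proportions (83.3 /
7.7 / 6.7 / 2.4%), the standardized loadings reproduce the configured
network (0.91 / 0.86 / 0.68 / 0.51) with excellent fit, and the latent-
intercept contrasts recover the configured group shifts (e.g. the
irritability-only group sits ≈ 0.55 anchor-units below the typically
developing group; the generating latent separation is 0.56 × the anchor
loading 0.91 ≈ 0.51, within sampling error).

A full end-to-end run (QC → winsorization → LCA → networks → invariance →
contrasts → regional mixed models → SSRT comparison) is available as
`stoplatent run` on a CSV bundle or `stoplatent.run_pipeline` in Python;
`stoplatent simulate` writes a synthetic bundle.

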