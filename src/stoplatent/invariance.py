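"""Multi-group measurement invariance and latent-intercept group contrasts.

The ladder fits configural, metric and scalar models bottom-up and rejects a
step only when BOTH delta-CFI > 0.01 AND delta-RMSEA > 0.015 (the
conjunctive large-sample rule). Under an attained scalar model the group
contrasts are differences of latent intercepts (reference group fixed at 0),
with delta-method standard errors from the observed information, Wald z
tests, Benjamini-Hochberg FDR within each factor's contrast family, and
Cohen's d defined as |difference| / pooled model-implied latent SD (a
documented convention; no standard formula reproduces published d values
from the printed estimates alone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cfa import (ConfirmatoryFactorAnalysis, FactorFit, FactorModelSpec,
                  FitIndices, fit_indices)

__all__ = [
    "fit_multigroup",
    "invariance_ladder",
    "LadderResult",
    "compare_latent_means",
    "contrast_table",
    "fdr_adjust",
    "cluster_robust_se",
]

LEVELS = ("configural", "metric", "scalar")


def fit_multigroup(spec: FactorModelSpec, betas, covariates=None,
                   groups=None, level: str = "configural") -> FactorFit:
    """Joint ML fit of the measurement model across groups at one level."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    est = ConfirmatoryFactorAnalysis(spec, level=level)
    est.fit(betas, groups=groups, X=covariates)
    return est.fit_


@dataclass
class LadderResult:
    fits: dict[str, FactorFit]
    indices: dict[str, FitIndices]
    deltas: pd.DataFrame
    attained: str

    def __repr__(self):
        return f"LadderResult(attained={self.attained!r})"


def invariance_ladder(spec: FactorModelSpec, betas, groups, covariates=None,
                      dcfi: float = 0.01, drmsea: float = 0.015) -> LadderResult:
    """Fit the configural -> metric -> scalar ladder and decide the level.

    A step is rejected only when delta-CFI > ``dcfi`` AND delta-RMSEA >
    ``drmsea`` (both conditions must hold); the ladder stops at the last
    non-rejected level.
    """
    fits: dict[str, FactorFit] = {}
    indices: dict[str, FitIndices] = {}
    rows = []
    attained = None
    prev = None
    for level in LEVELS:
        fit = fit_multigroup(spec, betas, covariates=covariates,
                             groups=groups, level=level)
        idx = fit_indices(fit)
        fits[level] = fit
        indices[level] = idx
        if prev is None:
            if not fit.converged:
                raise RuntimeError("configural model did not converge")
            rows.append({"level": level, "cfi": idx.cfi, "rmsea": idx.rmsea,
                         "delta_cfi": np.nan, "delta_rmsea": np.nan,
                         "rejected": False})
            attained = level
        else:
            d_cfi = indices[prev].cfi - idx.cfi
            d_rmsea = idx.rmsea - indices[prev].rmsea
            rejected = bool((d_cfi > dcfi) and (d_rmsea > drmsea))
            rows.append({"level": level, "cfi": idx.cfi, "rmsea": idx.rmsea,
                         "delta_cfi": d_cfi, "delta_rmsea": d_rmsea,
                         "rejected": rejected})
            if rejected:
                break
            attained = level
        prev = level
    return LadderResult(fits=fits, indices=indices,
                        deltas=pd.DataFrame(rows).set_index("level"),
                        attained=attained)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast_table(alphas: dict, ses: dict | None = None,
                   cov: np.ndarray | None = None,
                   pooled_sd: float = 1.0,
                   group_order: list | None = None) -> pd.DataFrame:
    """All pairwise latent-intercept contrasts for one factor.

    ``alphas`` maps group name -> latent intercept. Standard errors come
    either from a full joint covariance ``cov`` (ordered as ``group_order``)
    or per-group ``ses`` treated as independent; with neither, SE columns
    are NaN. Cohen's d = |difference| / ``pooled_sd``.
    """
    names = group_order if group_order is not None else list(alphas)
    rows = []
    for g1, g2 in combinations(names, 2):
        diff = alphas[g2] - alphas[g1]
        if cov is not None:
            i, j = names.index(g1), names.index(g2)
            var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
            se = np.sqrt(max(var, 0.0))
        elif ses is not None:
            se = np.sqrt(ses[g1] ** 2 + ses[g2] ** 2)
        else:
            se = np.nan
        z = diff / se if se and np.isfinite(se) and se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({
            "group_1": g1, "group_2": g2,
            "alpha_1": alphas[g1], "alpha_2": alphas[g2],
            "estimate": diff, "se": se, "z": z, "p_raw": p,
            "cohens_d": abs(diff) / pooled_sd,
        })
    out = pd.DataFrame(rows)
    finite = out["p_raw"].notna()
    out["p_fdr"] = np.nan
    if finite.any():
        out.loc[finite, "p_fdr"] = fdr_adjust(out.loc[finite, "p_raw"].to_numpy())
    return out


def compare_latent_means(fit: FactorFit, reference=None,
                         param_cov: np.ndarray | None = None,
                         allow_non_scalar: bool = False) -> pd.DataFrame:
    """Pairwise latent-intercept contrasts from a fitted scalar model.

    The FDR family is the set of pairwise contrasts within each factor.
    ``param_cov`` overrides the observed-information parameter covariance
    (e.g. with a cluster-robust version); point estimates are unaffected.
    """
    if fit.level != "scalar" and not allow_non_scalar:
        raise ValueError(
            "latent-mean comparison requires a scalar-invariant fit "
            "(pass allow_non_scalar=True to override)"
        )
    names = list(fit.group_names)
    if reference is None:
        reference = names[0]
    if reference not in names:
        raise ValueError(f"reference group {reference!r} not among {names}")
    if reference != names[0]:
        raise ValueError(
            f"the fitted reference (first) group is {names[0]!r}; refit with "
            f"groups ordered so that {reference!r} comes first"
        )
    m = len(fit.spec.factor_names)
    cov = param_cov if param_cov is not None else fit.param_cov()

    # pooled model-implied latent SD per factor
    N = fit.ns.sum()
    pooled_var = np.zeros(m)
    for g in range(len(names)):
        pooled_var += fit.ns[g] / N * fit.factor_variances(g)
    pooled_sd = np.sqrt(pooled_var)

    tables = []
    for f, fname in enumerate(fit.spec.factor_names):
        alphas = {}
        idx_of = {}
        for g, gname in enumerate(names):
            alphas[gname] = float(fit.alpha[g][f])
            sl = fit.alpha_slice(g)
            idx_of[gname] = None if sl is None else sl.start + f
        G = len(names)
        acov = np.zeros((G, G))
        for i, gi in enumerate(names):
            for j, gj in enumerate(names):
                ii, jj = idx_of[gi], idx_of[gj]
                if ii is not None and jj is not None:
                    acov[i, j] = cov[ii, jj]
        tab = contrast_table(alphas, cov=acov, pooled_sd=pooled_sd[f],
                             group_order=names)
        tab.insert(0, "factor", fname)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def cluster_robust_se(fit: FactorFit, cluster_ids) -> dict:
    """Cluster-robust (sandwich) replacement covariance and SEs.

    Returns a dict with the robust parameter covariance, per-parameter SEs,
    and the naive observed-information SEs for comparison. Estimates are
    unchanged; clusters may span groups.
    """
    robust = fit.cluster_robust_cov(np.asarray(cluster_ids))
    naive = fit.param_cov()
    names = fit.layout.param_names()
    return {
        "cov": robust,
        "se": pd.Series(np.sqrt(np.maximum(np.diag(robust), 0.0)), index=names),
        "se_naive": pd.Series(np.sqrt(np.maximum(np.diag(naive), 0.0)), index=names),
    }
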