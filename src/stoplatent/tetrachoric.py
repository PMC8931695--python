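"""Tetrachoric correlations and binary-item factor analysis.

Binary symptom items are modeled as thresholded bivariate-normal latent
responses. Each pairwise tetrachoric correlation is the ML estimate of the
latent correlation given thresholds fixed at the item margins; the item
factor model is then fitted to the tetrachoric matrix by unweighted least
squares (ULS) on the off-diagonal correlations. The reported chi-square,
(N - 1) * F_ULS, is an approximation (no weight-matrix correction) and is
labeled as such wherever surfaced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cfa import FactorModelSpec, FitIndices, _rmsea_ci

__all__ = [
    "tetrachoric_pair",
    "tetrachoric_matrix",
    "fit_cfa_binary",
    "BinaryFactorFit",
]

_RHO_CAP = 0.999


def tetrachoric_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """ML tetrachoric correlation of two binary vectors.

    Returns (rho, smoothed_flag); the flag is set when an empty 2x2 cell
    required a continuity correction (+0.5 to every cell) or the estimate
    hit the +-0.999 cap.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n11 = float(np.sum((x == 1) & (y == 1)))
    n10 = float(np.sum((x == 1) & (y == 0)))
    n01 = float(np.sum((x == 0) & (y == 1)))
    n00 = float(np.sum((x == 0) & (y == 0)))
    flagged = False
    if min(n11, n10, n01, n00) == 0:
        n11, n10, n01, n00 = n11 + 0.5, n10 + 0.5, n01 + 0.5, n00 + 0.5
        flagged = True
    n = n11 + n10 + n01 + n00
    p1 = (n11 + n10) / n
    p2 = (n11 + n01) / n
    # P(item = 1) = P(Z > tau)
    tau1 = stats.norm.ppf(1 - p1)
    tau2 = stats.norm.ppf(1 - p2)

    def cell_probs(rho):
        mvn = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        # P(Z1 > tau1, Z2 > tau2) = CDF at (-tau1, -tau2) by symmetry
        p11 = mvn.cdf([-tau1, -tau2])
        pa = 1 - stats.norm.cdf(tau1)
        pb = 1 - stats.norm.cdf(tau2)
        p10 = pa - p11
        p01 = pb - p11
        p00 = 1 - pa - pb + p11
        return np.clip([p11, p10, p01, p00], 1e-12, 1.0)

    def negloglik(rho):
        p = cell_probs(rho)
        return -(n11 * np.log(p[0]) + n10 * np.log(p[1])
                 + n01 * np.log(p[2]) + n00 * np.log(p[3]))

    res = optimize.minimize_scalar(
        negloglik, bounds=(-_RHO_CAP, _RHO_CAP), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    if abs(rho) >= _RHO_CAP - 1e-4:
        rho = float(np.sign(rho) * _RHO_CAP)
        flagged = True
    return rho, flagged


def tetrachoric_matrix(X) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise tetrachoric correlation matrix and smoothing flags."""
    cols = list(X.columns) if hasattr(X, "columns") else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    arr = np.asarray(X[cols] if hasattr(X, "columns") else X, float)
    k = arr.shape[1]
    R = np.eye(k)
    flags = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            rho, fl = tetrachoric_pair(arr[:, i], arr[:, j])
            R[i, j] = R[j, i] = rho
            flags[i, j] = flags[j, i] = fl
    return (pd.DataFrame(R, index=cols, columns=cols),
            pd.DataFrame(flags, index=cols, columns=cols))


@dataclass
class BinaryFactorFit:
    """ULS factor solution on a tetrachoric matrix, with approximate fit."""

    spec: FactorModelSpec
    loadings: pd.DataFrame            # standardized (correlation metric)
    phi: np.ndarray
    uniquenesses: np.ndarray
    tetrachoric: pd.DataFrame
    smoothing_flags: pd.DataFrame
    f_uls: float
    indices: FitIndices
    n: int


def _implied_corr(lam_vec, phi_free, spec: FactorModelSpec):
    k = len(spec.indicator_names)
    m = len(spec.factor_names)
    Lam = np.zeros((k, m))
    pattern = spec.pattern
    Lam[np.arange(k), pattern] = lam_vec
    Phi = np.eye(m)
    if m > 1:
        iu = np.triu_indices(m, k=1)
        Phi[iu] = phi_free
        Phi[(iu[1], iu[0])] = phi_free
    return Lam @ Phi @ Lam.T, Lam, Phi


def fit_cfa_binary(items, spec: FactorModelSpec) -> BinaryFactorFit:
    """Two-stage binary-item CFA: tetrachoric matrix, then ULS factor fit."""
    cols = spec.indicator_names
    X = items[cols] if hasattr(items, "columns") else pd.DataFrame(
        np.asarray(items, float), columns=cols
    )
    n = X.shape[0]
    R, flags = tetrachoric_matrix(X)
    Rm = R.to_numpy()
    k = len(cols)
    m = len(spec.factor_names)
    iu = np.triu_indices(k, k=1)
    n_phi = m * (m - 1) // 2

    def unpack(t):
        return t[:k], t[k:k + n_phi]

    def objective(t):
        lam, phi = unpack(t)
        implied, _, _ = _implied_corr(lam, phi, spec)
        return 0.5 * np.sum((Rm[iu] - implied[iu]) ** 2)

    t0 = np.concatenate([np.full(k, 0.6), np.full(n_phi, 0.3)])
    bounds = [(-0.995, 0.995)] * k + [(-0.95, 0.95)] * n_phi
    res = optimize.minimize(objective, t0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 2000, "ftol": 1e-14})
    lam, phi = unpack(res.x)
    implied, Lam, Phi = _implied_corr(lam, phi, spec)
    f_uls = float(res.fun)

    # approximate chi-square from the ULS discrepancy (documented approximation)
    n_moments = k * (k - 1) // 2
    df = n_moments - (k + n_phi)
    chi2_val = (n - 1) * f_uls
    f_base = 0.5 * np.sum(Rm[iu] ** 2)
    chi2_b = (n - 1) * f_base
    df_b = n_moments
    dm = max(chi2_val - df, 0.0)
    db = max(chi2_b - df_b, dm, 0.0)
    cfi = 1.0 if db == 0 else float(np.clip(1 - dm / db, 0, 1))
    if df_b > 0 and chi2_b / df_b > 1 and df > 0:
        tli = float(np.clip(
            ((chi2_b / df_b) - (chi2_val / df)) / ((chi2_b / df_b) - 1), 0, 1
        ))
    else:
        tli = 1.0
    rmsea = float(np.sqrt(dm / (df * n))) if df > 0 else 0.0
    srmr = float(np.sqrt(np.mean((Rm[iu] - implied[iu]) ** 2)))
    indices = FitIndices(
        chi2=float(chi2_val), df=int(max(df, 0)),
        p_value=float(stats.chi2.sf(chi2_val, df)) if df > 0 else 1.0,
        cfi=cfi, tli=tli, rmsea=rmsea,
        rmsea_ci=_rmsea_ci(chi2_val, df, n, 1) if df > 0 else (0.0, 0.0),
        srmr=srmr,
    )
    return BinaryFactorFit(
        spec=spec,
        loadings=pd.DataFrame(Lam, index=cols, columns=spec.factor_names),
        phi=Phi, uniquenesses=1.0 - np.sum(Lam**2 * np.diag(Phi), axis=1),
        tetrachoric=R, smoothing_flags=flags, f_uls=f_uls,
        indices=indices, n=n,
    )
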