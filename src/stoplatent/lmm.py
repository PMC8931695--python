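"""Region-level group comparisons with a site random intercept.

The model is y = X beta + u_site + e with u_site ~ N(0, sigma_s^2) and
e ~ N(0, sigma_e^2), estimated by REML with the variance ratio
gamma = sigma_s^2 / sigma_e^2 profiled out and optimized on a bounded
scalar search. The omnibus group test is a Wald F of the group dummy
coefficients with a Satterthwaite-style denominator df (per-eigencomponent
Satterthwaite df combined as in the lmerTest convention), and the effect
size is a semi-partial eta^2 = SS_group / SS_total computed on the
GLS-whitened scale. With fewer than two sites the model falls back to OLS
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .invariance import fdr_adjust

__all__ = [
    "RandomInterceptLMM",
    "LMMResult",
    "fit_lmm",
    "build_design",
    "region_scan",
    "sex_by_group_scan",
]


def build_design(labels, covariates: pd.DataFrame | None = None,
                 interaction: pd.Series | None = None):
    """Design matrix: intercept + group dummies (+ covariates, + interaction).

    Group dummies are coded against the first level in sorted order (or the
    categorical order if ``labels`` is categorical); categorical covariates
    are dummy-coded against their modal level. Returns
    (X, column names, group column indices, interaction column indices).
    """
    lab = pd.Series(labels).reset_index(drop=True)
    cat = lab.astype("category")
    levels = list(cat.cat.categories)
    n = len(lab)
    cols = [np.ones(n)]
    names = ["intercept"]
    group_idx = []
    for lev in levels[1:]:
        cols.append((lab == lev).to_numpy(float))
        names.append(f"group[{lev}]")
        group_idx.append(len(names) - 1)

    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            if c in ("subject_id",):
                continue
            s = cov[c]
            if pd.api.types.is_numeric_dtype(s):
                cols.append(s.to_numpy(float))
                names.append(c)
            else:
                modal = s.mode().iloc[0]
                for lev in sorted(x for x in s.unique() if x != modal):
                    cols.append((s == lev).to_numpy(float))
                    names.append(f"{c}[{lev}]")

    inter_idx = []
    if interaction is not None:
        s = pd.Series(interaction).reset_index(drop=True).astype("category")
        ilevels = list(s.cat.categories)
        if len(ilevels) < 2:
            raise ValueError("interaction variable is constant")
        main = []
        for lev in ilevels[1:]:
            cols.append((s == lev).to_numpy(float))
            names.append(f"sex[{lev}]")
            main.append(len(names) - 1)
        for glev in levels[1:]:
            gcol = (lab == glev).to_numpy(float)
            for ilev in ilevels[1:]:
                cols.append(gcol * (s == ilev).to_numpy(float))
                names.append(f"group[{glev}]:sex[{ilev}]")
                inter_idx.append(len(names) - 1)

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr
        _, _, piv = qr(X, pivoting=True, mode="economic")
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"singular design; aliased columns: {aliased}")
    return X, names, group_idx, inter_idx


@dataclass
class LMMResult:
    params: pd.Series
    site_var: float
    resid_var: float
    gamma: float
    f_stat: float
    df_num: int
    df_den: float
    p_value: float
    eta2: float
    ss_effect: float
    ss_total: float
    pairwise: pd.DataFrame | None
    n: int
    reml_criterion: float
    used_ols: bool = False
    param_cov: np.ndarray = field(default=None, repr=False)


class RandomInterceptLMM:
    """Profiled-REML linear mixed model with a single random intercept."""

    def __init__(self, max_gamma: float = 1e3):
        self.max_gamma = max_gamma

    def get_params(self, deep: bool = True) -> dict:
        return {"max_gamma": self.max_gamma}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- REML pieces --------------------------------------------------------

    @staticmethod
    def _site_blocks(site_ids):
        sites = pd.Series(site_ids).reset_index(drop=True)
        codes = sites.astype("category").cat.codes.to_numpy()
        n_sites = codes.max() + 1
        return codes, n_sites

    def _suff_stats(self, X, y, codes, n_sites):
        # per-site sums for the Woodbury forms
        n, p = X.shape
        XtX = X.T @ X
        Xty = X.T @ y
        yty = float(y @ y)
        Sx = np.zeros((n_sites, p))
        Sy = np.zeros(n_sites)
        np.add.at(Sx, codes, X)
        np.add.at(Sy, codes, y)
        counts = np.bincount(codes, minlength=n_sites).astype(float)
        return XtX, Xty, yty, Sx, Sy, counts

    @staticmethod
    def _gls(XtX, Xty, yty, Sx, Sy, counts, gamma):
        c = gamma / (1.0 + gamma * counts)
        A = XtX - (Sx * c[:, None]).T @ Sx
        b = Xty - Sx.T @ (c * Sy)
        q = yty - float(c @ Sy**2)
        beta = np.linalg.solve(A, b)
        rss = q - float(beta @ b)          # r' V^-1 r
        logdet_V = float(np.sum(np.log1p(gamma * counts)))
        sign, logdet_A = np.linalg.slogdet(A)
        return beta, A, rss, logdet_V, logdet_A

    def _reml_crit(self, gamma, stats_tuple, n, p):
        """-2 profiled REML log-likelihood (up to an additive constant)."""
        _, _, rss, logdet_V, logdet_A = self._gls(*stats_tuple, gamma)
        if rss <= 0:
            return np.inf
        return logdet_V + logdet_A + (n - p) * np.log(rss)

    def fit(self, X, y, site_ids) -> "RandomInterceptLMM":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        codes, n_sites = self._site_blocks(site_ids)
        if n_sites < 2:
            warnings.warn("fewer than 2 sites; falling back to OLS",
                          RuntimeWarning)
            gamma = 0.0
            st = self._suff_stats(X, y, codes, n_sites)
        else:
            st = self._suff_stats(X, y, codes, n_sites)
            res = optimize.minimize_scalar(
                lambda lg: self._reml_crit(np.exp(lg), st, n, p),
                bounds=(np.log(1e-8), np.log(self.max_gamma)),
                method="bounded", options={"xatol": 1e-8},
            )
            gamma = float(np.exp(res.x))
            if self._reml_crit(0.0, st, n, p) <= res.fun:
                gamma = 0.0
        beta, A, rss, logdet_V, _ = self._gls(*st, gamma)
        sigma_e2 = rss / (n - p)
        self.coef_ = beta
        self.gamma_ = gamma
        self.sigma_e2_ = float(sigma_e2)
        self.sigma_s2_ = float(gamma * sigma_e2)
        self.cov_beta_ = np.linalg.inv(A) * sigma_e2
        self.reml_criterion_ = float(self._reml_crit(gamma, st, n, p))
        self._st = st
        self._shape = (n, p)
        self._codes = codes
        self._n_sites = n_sites
        self._X, self._y = X, y
        return self

    # -- Satterthwaite machinery -------------------------------------------

    def _cov_beta_at(self, theta):
        """Var(beta) = (X' V(theta)^-1 X)^-1 with V in absolute units."""
        sigma_e2, sigma_s2 = theta
        gamma = sigma_s2 / sigma_e2
        XtX, Xty, yty, Sx, Sy, counts = self._st
        c = gamma / (1.0 + gamma * counts)
        A = XtX - (Sx * c[:, None]).T @ Sx
        return np.linalg.inv(A) * sigma_e2

    def _minus2_reml_at(self, theta):
        sigma_e2, sigma_s2 = theta
        if sigma_e2 <= 0 or sigma_s2 < 0:
            return np.inf
        n, p = self._shape
        gamma = sigma_s2 / sigma_e2
        XtX, Xty, yty, Sx, Sy, counts = self._st
        beta, A, rss, logdet_V_unit, logdet_A_unit = self._gls(
            XtX, Xty, yty, Sx, Sy, counts, gamma
        )
        logdet_V = n * np.log(sigma_e2) + logdet_V_unit
        logdet_A = logdet_A_unit - p * np.log(sigma_e2)
        return logdet_V + logdet_A + rss / sigma_e2

    def _theta_cov(self):
        """Asymptotic covariance of (sigma_e^2, sigma_s^2) from the REML Hessian."""
        if self.sigma_e2_ <= 0:  # degenerate (e.g. constant outcome)
            return np.full((2, 2), np.nan)
        theta = np.array([self.sigma_e2_, max(self.sigma_s2_, 1e-10)])
        h = 1e-5 * np.maximum(np.abs(theta), 1e-6)
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                fpp = self._minus2_reml_at(theta + ei + ej)
                fpm = self._minus2_reml_at(theta + ei - ej)
                fmp = self._minus2_reml_at(theta - ei + ej)
                fmm = self._minus2_reml_at(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            return np.linalg.inv(0.5 * H)
        except np.linalg.LinAlgError:
            return np.full((2, 2), np.nan)

    def satterthwaite_df(self, contrast: np.ndarray,
                         theta_cov: np.ndarray | None = None) -> float:
        """Satterthwaite denominator df for a single contrast c' beta."""
        n, p = self._shape
        if self.gamma_ == 0.0 or self._n_sites < 2:
            return float(n - p)
        theta = np.array([self.sigma_e2_, max(self.sigma_s2_, 1e-10)])
        if theta_cov is None:
            theta_cov = self._theta_cov()
        if not np.all(np.isfinite(theta_cov)):
            return float(n - p)

        def f(th):
            C = self._cov_beta_at(th)
            return float(contrast @ C @ contrast)

        h = 1e-5 * np.maximum(np.abs(theta), 1e-6)
        grad = np.array([
            (f(theta + np.array([h[0], 0])) - f(theta - np.array([h[0], 0]))) / (2 * h[0]),
            (f(theta + np.array([0, h[1]])) - f(theta - np.array([0, h[1]]))) / (2 * h[1]),
        ])
        var_f = float(grad @ theta_cov @ grad)
        f0 = f(theta)
        if var_f <= 0 or f0 <= 0:
            return float(n - p)
        nu = 2 * f0**2 / var_f
        return float(np.clip(nu, 1.0, n - p))


def _omnibus_f(model: RandomInterceptLMM, L: np.ndarray):
    """Wald F of L beta = 0 with lmerTest-style combined Satterthwaite ddf."""
    beta = model.coef_
    C = model.cov_beta_
    M = L @ C @ L.T
    q = L.shape[0]
    Minv = np.linalg.inv(M)
    F = float(beta @ L.T @ Minv @ L @ beta) / q
    n, p = model._shape
    if model.gamma_ == 0.0 or model._n_sites < 2:
        return F, q, float(n - p)
    theta_cov = model._theta_cov()
    evals, evecs = np.linalg.eigh(M)
    nus = []
    for i in range(q):
        li = evecs[:, i] @ L
        nus.append(model.satterthwaite_df(li, theta_cov=theta_cov))
    nus = np.array(nus)
    good = nus > 2
    if not good.any():
        return F, q, float(n - p)
    E = float(np.sum(nus[good] / (nus[good] - 2)))
    ddf = 2 * E / (E - q) if E > q else float(n - p)
    return F, q, float(np.clip(ddf, 1.0, n - p))


def fit_lmm(outcome, group_labels, covariates=None, site_ids=None,
            interaction=None, test: str = "group") -> LMMResult:
    """Site-random-intercept comparison of an outcome across groups.

    ``test='group'`` tests the group dummies (omnibus F); with an
    ``interaction`` series and ``test='interaction'`` the group-by-
    interaction terms are tested instead. Pairwise group contrasts carry
    per-contrast Satterthwaite df and BH-FDR adjusted p-values.
    """
    y = np.asarray(outcome, float)
    ok = np.isfinite(y)
    lab = pd.Series(group_labels).reset_index(drop=True)
    cov = (pd.DataFrame(covariates).reset_index(drop=True)
           if covariates is not None else None)
    inter = (pd.Series(interaction).reset_index(drop=True)
             if interaction is not None else None)
    sid = (pd.Series(site_ids).reset_index(drop=True)
           if site_ids is not None else pd.Series(np.zeros(len(y), int)))
    if not ok.all():
        y = y[ok]
        lab = lab[ok].reset_index(drop=True)
        cov = cov[ok].reset_index(drop=True) if cov is not None else None
        inter = inter[ok].reset_index(drop=True) if inter is not None else None
        sid = sid[ok].reset_index(drop=True)

    X, names, group_idx, inter_idx = build_design(lab, cov, inter)
    model = RandomInterceptLMM().fit(X, y, sid)
    n, p = X.shape

    test_idx = inter_idx if test == "interaction" else group_idx
    if not test_idx:
        raise ValueError(f"no columns to test for {test!r}")
    L = np.zeros((len(test_idx), p))
    for r, j in enumerate(test_idx):
        L[r, j] = 1.0
    if np.allclose(y, y[0]):
        F, q, ddf, p_val = 0.0, len(test_idx), float(n - p), 1.0
    else:
        F, q, ddf = _omnibus_f(model, L)
        p_val = float(stats.f.sf(F, q, ddf))

    # whitened sums of squares for the semi-partial eta^2
    gamma = model.gamma_
    codes = model._codes
    counts = np.bincount(codes, minlength=model._n_sites).astype(float)
    a = 1.0 / np.sqrt(1.0 + gamma * counts)

    def whiten(M):
        M = np.atleast_2d(M.T).T if M.ndim == 1 else M
        site_means = np.zeros((model._n_sites, M.shape[1]))
        np.add.at(site_means, codes, M)
        site_means /= counts[:, None]
        return M - ((1.0 - a)[codes])[:, None] * site_means[codes]

    yw = whiten(y[:, None]).ravel()

    def sse(cols):
        Xw = whiten(X[:, cols])
        b, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ b
        return float(r @ r)

    all_cols = list(range(p))
    red_cols = [j for j in all_cols if j not in test_idx]
    sse_full = sse(all_cols)
    sse_red = sse(red_cols)
    ss_tot = sse([0])
    ss_effect = max(sse_red - sse_full, 0.0)
    eta2 = ss_effect / ss_tot if ss_tot > 0 else 0.0

    # pairwise group contrasts
    levels = list(lab.astype("category").cat.categories)
    pair_rows = []
    theta_cov = None
    for g1, g2 in combinations(levels, 2):
        c = np.zeros(p)
        if g1 != levels[0]:
            c[names.index(f"group[{g1}]")] = -1.0
        if g2 != levels[0]:
            c[names.index(f"group[{g2}]")] = 1.0
        est = float(c @ model.coef_)
        se = float(np.sqrt(c @ model.cov_beta_ @ c))
        if model.gamma_ > 0 and model._n_sites >= 2:
            if theta_cov is None:
                theta_cov = model._theta_cov()
            nu = model.satterthwaite_df(c, theta_cov=theta_cov)
        else:
            nu = float(n - p)
        t = est / se if se > 0 else np.nan
        p_pair = 2 * stats.t.sf(abs(t), nu) if np.isfinite(t) else np.nan
        pair_rows.append({"group_1": g1, "group_2": g2, "estimate": est,
                          "se": se, "t": t, "df": nu, "p_raw": p_pair})
    pairwise = pd.DataFrame(pair_rows)
    finite = pairwise["p_raw"].notna()
    pairwise["p_fdr"] = np.nan
    if finite.any():
        pairwise.loc[finite, "p_fdr"] = fdr_adjust(
            pairwise.loc[finite, "p_raw"].to_numpy()
        )

    return LMMResult(
        params=pd.Series(model.coef_, index=names),
        site_var=model.sigma_s2_, resid_var=model.sigma_e2_,
        gamma=model.gamma_, f_stat=F, df_num=q, df_den=ddf,
        p_value=p_val, eta2=eta2, ss_effect=ss_effect, ss_total=ss_tot,
        pairwise=pairwise, n=n, reml_criterion=model.reml_criterion_,
        used_ols=(model._n_sites < 2), param_cov=model.cov_beta_,
    )


def region_scan(betas: pd.DataFrame, regions: list[str], labels,
                covariates=None, site_ids=None,
                alpha: float = 0.05) -> pd.DataFrame:
    """Per-region mixed-model omnibus tests with BH-FDR across regions."""
    missing = [r for r in regions if r not in betas.columns]
    if missing:
        raise ValueError(f"regions absent from betas: {missing}")
    rows = []
    results = {}
    for region in regions:
        res = fit_lmm(betas[region].to_numpy(float), labels,
                      covariates=covariates, site_ids=site_ids)
        results[region] = res
        rows.append({
            "region": region, "ss_group": res.ss_effect,
            "ms_group": res.ss_effect / res.df_num,
            "num_df": res.df_num, "den_df": res.df_den,
            "F": res.f_stat, "p_raw": res.p_value, "eta2": res.eta2,
        })
    table = pd.DataFrame(rows).set_index("region")
    table["p_fdr"] = fdr_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_fdr"] < alpha
    table.attrs["fits"] = results
    return table


def sex_by_group_scan(betas: pd.DataFrame, regions: list[str], labels, sex,
                      covariates=None, site_ids=None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-region sex-by-group interaction F tests with BH-FDR."""
    missing = [r for r in regions if r not in betas.columns]
    if missing:
        raise ValueError(f"regions absent from betas: {missing}")
    sex_s = pd.Series(sex).reset_index(drop=True)
    lab_s = pd.Series(labels).reset_index(drop=True)
    if sex_s.nunique() < 2:
        raise ValueError("sex is constant; interaction inestimable")
    tab = pd.crosstab(lab_s, sex_s)
    empty_cells = (tab == 0).any(axis=1)
    skipped_groups = list(tab.index[empty_cells])
    if skipped_groups:
        warnings.warn(
            f"groups with an empty sex cell skipped: {skipped_groups}",
            RuntimeWarning,
        )
        keep = ~lab_s.isin(skipped_groups).to_numpy()
    else:
        keep = np.ones(len(lab_s), bool)
    rows = []
    for region in regions:
        res = fit_lmm(
            betas[region].to_numpy(float)[keep], lab_s[keep],
            covariates=(pd.DataFrame(covariates)[keep]
                        if covariates is not None else None),
            site_ids=(pd.Series(site_ids)[keep]
                      if site_ids is not None else None),
            interaction=sex_s[keep], test="interaction",
        )
        rows.append({"region": region, "F": res.f_stat,
                     "num_df": res.df_num, "den_df": res.df_den,
                     "p_raw": res.p_value})
    table = pd.DataFrame(rows).set_index("region")
    table["p_fdr"] = fdr_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_fdr"] < alpha
    if skipped_groups:
        table.attrs["skipped_groups"] = skipped_groups
    return table
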