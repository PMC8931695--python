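"""Confirmatory factor analysis with covariance + mean structure.

Implements normal-theory maximum likelihood for single- and multi-group
measurement models of the form

    eta = alpha_g + Gamma x + zeta,   zeta ~ N(0, Psi_g)
    y   = nu_g + Lambda_g eta + eps,  eps  ~ N(0, diag(theta_g))

where each indicator loads on exactly one factor (simple structure),
covariates enter as exogenous predictors of the factors (MIMIC), and the
group levels of the measurement-invariance ladder are expressed as equality
constraints: configural (all measurement parameters group-specific, latent
means fixed at 0), metric (loadings equated), scalar (loadings and
intercepts equated, latent means free except in the reference group).

Identification fixes the first loading of each factor to 1 with the factor
(residual) variance free; standardized estimates are computed post hoc.
The model chi-square is N * F_ML at the optimum, the standard discrepancy
form; fit indices (CFI / TLI / RMSEA with 90% CI / SRMR) follow the usual
definitions, with the RMSEA carrying the multi-group G multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FactorModelSpec",
    "FactorFit",
    "FitIndices",
    "ConfirmatoryFactorAnalysis",
    "fit_cfa",
    "fit_indices",
    "rmsea_value",
    "cfi_tli",
]

_BIG = 1e10


@dataclass
class FactorModelSpec:
    """Simple-structure factor model: factor -> indicator list, plus covariates."""

    factors: dict[str, list[str]]
    covariates: tuple[str, ...] = ()
    min_indicators: int = 3

    def __post_init__(self):
        seen: set[str] = set()
        for name, inds in self.factors.items():
            if len(inds) < self.min_indicators:
                raise ValueError(
                    f"factor {name!r} has {len(inds)} indicators; "
                    f"confirmatory specs need >= {self.min_indicators}"
                )
            for ind in inds:
                if ind in seen:
                    raise ValueError(f"indicator {ind!r} loads on more than one factor")
                seen.add(ind)

    @property
    def indicator_names(self) -> list[str]:
        return [i for inds in self.factors.values() for i in inds]

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors.keys())

    @property
    def pattern(self) -> np.ndarray:
        """Factor index of each indicator (simple structure)."""
        out = []
        for f, inds in enumerate(self.factors.values()):
            out.extend([f] * len(inds))
        return np.array(out)

    @property
    def anchors(self) -> np.ndarray:
        """Row index of the unit-loading anchor indicator of each factor."""
        idx, pos = [], 0
        for inds in self.factors.values():
            idx.append(pos)
            pos += len(inds)
        return np.array(idx)


class _Layout:
    """Free-parameter bookkeeping for one constraint level."""

    def __init__(self, k: int, m: int, q: int, G: int, level: str):
        self.k, self.m, self.q, self.G, self.level = k, m, q, G, level
        if G == 1:
            level = "single"
            self.level = level
        shared_lam = level in ("single", "metric", "scalar")
        shared_nu = level in ("single", "scalar")
        shared_gamma = level in ("single", "metric", "scalar")
        self.segments: list[tuple[str, int | None, int]] = []

        def add(name, groups, size):
            for g in groups:
                self.segments.append((name, g, size))

        n_lam = k - m
        n_psi = m * (m + 1) // 2
        add("lam", [None] if shared_lam else range(G), n_lam)
        add("nu", [None] if shared_nu else range(G), k)
        add("theta", range(G), k)
        add("psi", range(G), n_psi)
        if q:
            add("gamma", [None] if shared_gamma else range(G), m * q)
        if level == "scalar" and G > 1:
            add("alpha", range(1, G), m)
        self.slices = {}
        pos = 0
        for name, g, size in self.segments:
            self.slices[(name, g)] = slice(pos, pos + size)
            pos += size
        self.n_free = pos

    def get(self, theta: np.ndarray, name: str, g: int):
        key = (name, g) if (name, g) in self.slices else (name, None)
        if key not in self.slices:
            return None
        return theta[self.slices[key]]

    def param_names(self) -> list[str]:
        names = []
        for name, g, size in self.segments:
            tag = "" if g is None else f"_g{g}"
            names.extend([f"{name}{tag}[{i}]" for i in range(size)])
        return names


def _psi_from_chol(p: np.ndarray, m: int) -> np.ndarray:
    L = np.zeros((m, m))
    L[np.diag_indices(m)] = np.exp(np.clip(p[:m], -20, 20))
    if m > 1:
        L[np.tril_indices(m, k=-1)] = p[m:]
    return L @ L.T


def _chol_params(psi: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(psi)
    m = psi.shape[0]
    out = np.empty(m * (m + 1) // 2)
    out[:m] = np.log(np.diag(L))
    if m > 1:
        out[m:] = L[np.tril_indices(m, k=-1)]
    return out


@dataclass
class FitIndices:
    chi2: float
    df: int
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float

    def as_dict(self) -> dict:
        return {
            "chi2": self.chi2, "df": self.df, "p_value": self.p_value,
            "cfi": self.cfi, "tli": self.tli, "rmsea": self.rmsea,
            "rmsea_lo": self.rmsea_ci[0], "rmsea_hi": self.rmsea_ci[1],
            "srmr": self.srmr,
        }


@dataclass
class FactorFit:
    """Fitted measurement model (one constraint level, one or more groups)."""

    spec: FactorModelSpec
    level: str
    group_names: list
    ns: np.ndarray
    loadings: list[np.ndarray]          # per group, (k, m) unstandardized
    intercepts: list[np.ndarray]        # per group nu
    uniquenesses: list[np.ndarray]      # per group theta (may be < 0: Heywood)
    psi: list[np.ndarray]               # per group factor (residual) covariance
    alpha: list[np.ndarray]             # per group latent means (reference 0)
    gamma: list[np.ndarray]             # per group (m, q) covariate effects
    loglik: float
    chi2: float
    df: int
    n: int
    converged: bool
    heywood: bool
    f_min: float
    layout: _Layout = field(repr=False)
    theta_free: np.ndarray = field(repr=False)
    _data: list[tuple[np.ndarray, np.ndarray | None]] = field(repr=False)
    _moments: list[tuple[np.ndarray, np.ndarray]] = field(repr=False)
    _param_cov: np.ndarray | None = field(default=None, repr=False)
    row_index: np.ndarray | None = field(default=None, repr=False)

    # -- reporting ----------------------------------------------------------

    def factor_variances(self, g: int = 0) -> np.ndarray:
        """Model-implied factor variances Var(eta) = Gamma Sxx Gamma' + Psi."""
        lam, psi, gam = self.loadings[g], self.psi[g], self.gamma[g]
        if gam.size:
            y, x = self._data[g]
            Sxx = np.atleast_2d(np.cov(x, rowvar=False, bias=True))
            B = gam @ Sxx @ gam.T + psi
        else:
            B = psi
        return np.diag(B)

    def implied_cov(self, g: int = 0) -> np.ndarray:
        """Model-implied indicator covariance for group g."""
        lam, psi, gam = self.loadings[g], self.psi[g], self.gamma[g]
        if gam.size:
            _, x = self._data[g]
            Sxx = np.atleast_2d(np.cov(x, rowvar=False, bias=True))
            B = gam @ Sxx @ gam.T + psi
        else:
            B = psi
        return lam @ B @ lam.T + np.diag(self.uniquenesses[g])

    def standardized_loadings(self, g: int = 0) -> pd.DataFrame:
        lam = self.loadings[g]
        fvar = self.factor_variances(g)
        # floor guards the degenerate zero-uniqueness (Heywood-adjacent) limit
        sd_y = np.sqrt(np.maximum(np.diag(self.implied_cov(g)), 1e-12))
        std = lam * np.sqrt(fvar)[None, :] / sd_y[:, None]
        return pd.DataFrame(std, index=self.spec.indicator_names,
                            columns=self.spec.factor_names)

    def srmr(self) -> float:
        """Root mean square standardized covariance residual (pooled over groups)."""
        total, wsum = 0.0, 0.0
        for g, (y, _) in enumerate(self._data):
            S = np.cov(y, rowvar=False, bias=True)
            Sigma = self.implied_cov(g)
            d = np.sqrt(np.diag(S))
            res = (S - Sigma) / np.outer(d, d)
            iu = np.triu_indices(S.shape[0])
            w = self.ns[g] / self.ns.sum()
            total += w * np.mean(res[iu] ** 2)
            wsum += w
        return float(np.sqrt(total / wsum))

    # -- likelihood / standard errors --------------------------------------

    def casewise_loglik(self, theta_free: np.ndarray | None = None) -> np.ndarray:
        """Per-subject multivariate-normal log-likelihood contributions."""
        theta = self.theta_free if theta_free is None else theta_free
        out = []
        cfa = ConfirmatoryFactorAnalysis(self.spec, level=self.level)
        for g, (y, x) in enumerate(self._data):
            Sigma, mu = cfa._implied(theta, self.layout, g, self._moments[g])
            z = np.column_stack([y, x]) if x is not None else y
            try:
                from scipy.linalg import cho_factor, cho_solve
                c, low = cho_factor(Sigma, lower=True)
            except np.linalg.LinAlgError:
                out.append(np.full(z.shape[0], -np.inf))
                continue
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            d = z - mu
            sol = cho_solve((c, low), d.T).T
            out.append(-0.5 * (z.shape[1] * np.log(2 * np.pi) + logdet
                               + np.einsum("ij,ij->i", d, sol)))
        return np.concatenate(out)

    def score_matrix(self, h: float = 1e-5) -> np.ndarray:
        """Casewise score matrix (n, p) by central differences."""
        p = self.layout.n_free
        base = self.theta_free
        S = np.empty((self.n, p))
        for j in range(p):
            step = h * max(1.0, abs(base[j]))
            up, dn = base.copy(), base.copy()
            up[j] += step
            dn[j] -= step
            S[:, j] = (self.casewise_loglik(up) - self.casewise_loglik(dn)) / (2 * step)
        return S

    def hessian(self, h: float = 1e-4) -> np.ndarray:
        """Numeric Hessian of the total log-likelihood at the optimum."""
        p = self.layout.n_free
        base = self.theta_free

        def total(t):
            return float(self.casewise_loglik(t).sum())

        H = np.empty((p, p))
        steps = np.array([h * max(1.0, abs(b)) for b in base])
        f0 = total(base)
        fp = np.empty(p)
        fm = np.empty(p)
        for i in range(p):
            e = np.zeros(p)
            e[i] = steps[i]
            fp[i] = total(base + e)
            fm[i] = total(base - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
        for i in range(p):
            for j in range(i + 1, p):
                e_i = np.zeros(p); e_i[i] = steps[i]
                e_j = np.zeros(p); e_j[j] = steps[j]
                fpp = total(base + e_i + e_j)
                fmm = total(base - e_i - e_j)
                H[i, j] = H[j, i] = (
                    fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
                ) / (2 * steps[i] * steps[j])
        return H

    def param_cov(self) -> np.ndarray:
        """Observed-information covariance of the free parameters."""
        if self._param_cov is None:
            H = self.hessian()
            self._param_cov = np.linalg.pinv(-H)
        return self._param_cov

    def cluster_robust_cov(self, cluster_ids: np.ndarray) -> np.ndarray:
        """Sandwich covariance with cluster-summed scores.

        Point estimates are unchanged; only the covariance is replaced.
        Clusters spanning groups are allowed; ``cluster_ids`` follow the
        original row order of the data passed to ``fit`` (the permutation
        into the internal group-sorted order is applied here).
        """
        S = self.score_matrix()
        ids = np.asarray(cluster_ids)
        if ids.shape[0] != S.shape[0]:
            raise ValueError("cluster_ids length must match the number of subjects")
        ids = ids[self.row_index]
        A_inv = self.param_cov()
        uniq, inv = np.unique(ids, return_inverse=True)
        Sc = np.zeros((uniq.size, S.shape[1]))
        np.add.at(Sc, inv, S)
        B = Sc.T @ Sc
        return A_inv @ B @ A_inv

    def alpha_slice(self, g: int) -> slice | None:
        key = ("alpha", g)
        return self.layout.slices.get(key)


class ConfirmatoryFactorAnalysis:
    """sklearn-style estimator for (multi-group) confirmatory factor models.

    Parameters
    ----------
    spec : FactorModelSpec
    level : {'single', 'configural', 'metric', 'scalar'}
        Constraint level; 'single' is forced when only one group is present.
    max_iter : int
        Optimizer iteration cap (L-BFGS-B on the ML discrepancy).
    """

    def __init__(self, spec: FactorModelSpec, level: str = "single",
                 max_iter: int = 2000, tol: float = 1e-10):
        self.spec = spec
        self.level = level
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec, "level": self.level,
                "max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- model structure ----------------------------------------------------

    def _lambda(self, lam_free: np.ndarray) -> np.ndarray:
        k = len(self.spec.indicator_names)
        m = len(self.spec.factor_names)
        pattern = self.spec.pattern
        anchors = self.spec.anchors
        Lam = np.zeros((k, m))
        Lam[anchors, np.arange(m)] = 1.0
        free_rows = np.setdiff1d(np.arange(k), anchors)
        Lam[free_rows, pattern[free_rows]] = lam_free
        return Lam

    def _group_params(self, theta, layout, g):
        m = len(self.spec.factor_names)
        q = len(self.spec.covariates)
        lam = self._lambda(layout.get(theta, "lam", g))
        nu = layout.get(theta, "nu", g)
        th = layout.get(theta, "theta", g)
        psi = _psi_from_chol(layout.get(theta, "psi", g), m)
        gam = (layout.get(theta, "gamma", g).reshape(m, q)
               if q else np.zeros((m, 0)))
        al = layout.get(theta, "alpha", g)
        alpha = np.zeros(m) if al is None else al
        return lam, nu, th, psi, gam, alpha

    def _implied(self, theta, layout, g, xmom):
        """Joint implied (Sigma, mu) over (y, x) for group g."""
        Sxx, mx = xmom
        lam, nu, th, psi, gam, alpha = self._group_params(theta, layout, g)
        q = len(self.spec.covariates)
        if q:
            B = gam @ Sxx @ gam.T + psi
            Syy = lam @ B @ lam.T + np.diag(th)
            Syx = lam @ gam @ Sxx
            Sigma = np.block([[Syy, Syx], [Syx.T, Sxx]])
            mu = np.concatenate([nu + lam @ (alpha + gam @ mx), mx])
        else:
            Sigma = lam @ psi @ lam.T + np.diag(th)
            mu = nu + lam @ alpha
        return Sigma, mu

    # -- discrepancy --------------------------------------------------------

    def _discrepancy(self, theta, layout, sample):
        from scipy.linalg import cho_factor, cho_solve
        F = 0.0
        N = sum(s["n"] for s in sample)
        for g, s in enumerate(sample):
            Sigma, mu = self._implied(theta, layout, g, s["xmom"])
            try:
                # Cholesky both tests positive definiteness (a positive
                # determinant alone does not) and gives the log-determinant
                c, low = cho_factor(Sigma, lower=True)
            except np.linalg.LinAlgError:
                return _BIG
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            if not np.isfinite(logdet):
                return _BIG
            Sinv_S = cho_solve((c, low), s["S"])
            d = s["mbar"] - mu
            quad = float(d @ cho_solve((c, low), d))
            Fg = (logdet - s["logdet_S"] + np.trace(Sinv_S)
                  - s["P"] + quad)
            F += s["n"] / N * Fg
        return F if np.isfinite(F) else _BIG

    def _start_values(self, layout, sample):
        spec = self.spec
        k = len(spec.indicator_names)
        m = len(spec.factor_names)
        q = len(spec.covariates)
        theta0 = np.zeros(layout.n_free)
        pooled_S = sum(s["n"] * s["S"][:k, :k] for s in sample) / sum(s["n"] for s in sample)
        pooled_m = sum(s["n"] * s["mbar"][:k] for s in sample) / sum(s["n"] for s in sample)

        def seg_start(name, g):
            S = pooled_S if g is None else sample[g]["S"][:k, :k]
            mbar = pooled_m if g is None else sample[g]["mbar"][:k]
            if name == "lam":
                vals = []
                for f, inds in enumerate(spec.factors.values()):
                    rows = [spec.indicator_names.index(i) for i in inds]
                    a = rows[0]
                    psi0 = max(0.5 * S[a, a], 1e-3)
                    for r in rows[1:]:
                        vals.append(np.clip(S[r, a] / psi0, -5, 5))
                return np.array(vals)
            if name == "nu":
                return mbar.copy()
            if name == "theta":
                return 0.5 * np.diag(S)
            if name == "psi":
                psi0 = np.eye(m)
                for f, inds in enumerate(spec.factors.values()):
                    a = spec.indicator_names.index(inds[0])
                    psi0[f, f] = max(0.5 * S[a, a], 1e-3)
                return _chol_params(psi0)
            if name == "gamma":
                return np.zeros(m * q)
            if name == "alpha":
                return np.zeros(m)
            raise KeyError(name)

        for name, g, size in layout.segments:
            theta0[layout.slices[(name, g)]] = seg_start(name, g)
        return theta0

    # -- fitting ------------------------------------------------------------

    def fit(self, Y, groups=None, X=None) -> "ConfirmatoryFactorAnalysis":
        spec = self.spec
        inds = spec.indicator_names
        if hasattr(Y, "columns"):
            missing = [c for c in inds if c not in Y.columns]
            if missing:
                raise ValueError(f"indicators absent from data: {missing}")
            Ymat = Y[inds].to_numpy(dtype=float)
        else:
            Ymat = np.asarray(Y, dtype=float)
        if X is not None and len(spec.covariates):
            Xmat = (X[list(spec.covariates)].to_numpy(dtype=float)
                    if hasattr(X, "columns") else np.asarray(X, float))
        elif len(spec.covariates):
            raise ValueError("spec declares covariates but none were supplied")
        else:
            Xmat = None

        k = len(inds)
        m = len(spec.factor_names)
        q = len(spec.covariates)
        if groups is None:
            groups = np.zeros(Ymat.shape[0], dtype=int)
        groups_s = pd.Series(groups).reset_index(drop=True)
        if isinstance(groups_s.dtype, pd.CategoricalDtype):
            # categorical ordering controls the group order (first = reference)
            group_names = [c for c in groups_s.cat.categories
                           if (groups_s == c).any()]
        else:
            group_names = list(pd.unique(groups_s))
        groups = np.asarray(groups_s)
        G = len(group_names)
        level = self.level if G > 1 else "single"
        layout = _Layout(k, m, q, G, level)

        sample = []
        data = []
        moments = []
        row_chunks = []
        for name in group_names:
            mask = groups == name
            row_chunks.append(np.where(mask)[0])
            y = Ymat[mask]
            if y.shape[0] <= k:
                raise ValueError(
                    f"group {name!r} has n={y.shape[0]} <= {k} indicators"
                )
            x = Xmat[mask] if Xmat is not None else None
            z = np.column_stack([y, x]) if x is not None else y
            S = np.cov(z, rowvar=False, bias=True)
            mbar = z.mean(axis=0)
            if x is not None:
                Sxx = np.atleast_2d(np.cov(x, rowvar=False, bias=True))
                mx = x.mean(axis=0)
            else:
                Sxx, mx = np.zeros((0, 0)), np.zeros(0)
            sign, logdet_S = np.linalg.slogdet(S)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    f"singular sample covariance in group {name!r}"
                )
            sample.append({
                "n": y.shape[0], "S": S, "mbar": mbar,
                "logdet_S": logdet_S, "P": z.shape[1], "xmom": (Sxx, mx),
            })
            data.append((y, x))
            moments.append((Sxx, mx))

        theta0 = self._start_values(layout, sample)
        res = optimize.minimize(
            self._discrepancy, theta0, args=(layout, sample),
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol,
                     "gtol": 1e-9, "maxfun": 10 * self.max_iter},
        )
        if not res.success or res.fun > 0.5:
            # near-singular samples put the optimum in a narrow curved
            # valley that defeats the quasi-Newton path; polish with a
            # simplex pass and re-sharpen
            res2 = optimize.minimize(
                self._discrepancy, res.x, args=(layout, sample),
                method="Nelder-Mead",
                options={"maxiter": 20000, "maxfev": 20000,
                         "xatol": 1e-12, "fatol": 1e-14},
            )
            res3 = optimize.minimize(
                self._discrepancy, res2.x, args=(layout, sample),
                method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol,
                         "gtol": 1e-9},
            )
            res = min((res, res2, res3), key=lambda r: r.fun)
        theta = res.x
        N = sum(s["n"] for s in sample)
        f_min = max(float(res.fun), 0.0)

        # degrees of freedom: joint moments minus free parameters (the
        # saturated x-block moments are counted on both sides)
        P = k + q
        n_moments = G * (P * (P + 3) // 2)
        n_free = layout.n_free + G * (q + q * (q + 1) // 2)
        df = n_moments - n_free

        loadings, intercepts, uniq, psis, alphas, gammas = [], [], [], [], [], []
        for g in range(G):
            lam, nu, th, psi, gam, alpha = self._group_params(theta, layout, g)
            loadings.append(lam)
            intercepts.append(nu)
            uniq.append(th)
            psis.append(psi)
            gammas.append(gam)
            alphas.append(alpha)

        fit = FactorFit(
            spec=spec, level=level, group_names=group_names,
            ns=np.array([s["n"] for s in sample]),
            loadings=loadings, intercepts=intercepts, uniquenesses=uniq,
            psi=psis, alpha=alphas, gamma=gammas,
            loglik=np.nan, chi2=N * f_min, df=df, n=N,
            converged=bool(res.success), heywood=bool(min(t.min() for t in uniq) < 0),
            f_min=f_min, layout=layout, theta_free=theta,
            _data=data, _moments=moments,
            row_index=np.concatenate(row_chunks),
        )
        fit.loglik = float(fit.casewise_loglik().sum())
        self.fit_ = fit
        return self

    @property
    def result_(self) -> FactorFit:
        return self.fit_


def fit_cfa(spec: FactorModelSpec, betas, covariates=None, group=None,
            level: str = "single") -> FactorFit:
    """Fit a confirmatory factor model; returns the :class:`FactorFit`."""
    est = ConfirmatoryFactorAnalysis(spec, level=level)
    est.fit(betas, groups=group, X=covariates)
    return est.fit_


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------

def _baseline_chi2(fit: FactorFit) -> tuple[float, int]:
    """Independence baseline: diagonal indicator covariance, free means,
    saturated covariate block, zero indicator-covariate covariance."""
    k = len(fit.spec.indicator_names)
    q = len(fit.spec.covariates)
    N = fit.n
    G = len(fit.group_names)
    F = 0.0
    for g, (y, x) in enumerate(fit._data):
        z = np.column_stack([y, x]) if x is not None else y
        S = np.cov(z, rowvar=False, bias=True)
        _, logdet_S = np.linalg.slogdet(S)
        logdet_B = float(np.sum(np.log(np.diag(S)[:k])))
        if q:
            Sxx = np.atleast_2d(np.cov(x, rowvar=False, bias=True))
            logdet_B += np.linalg.slogdet(Sxx)[1]
        F += fit.ns[g] / N * (logdet_B - logdet_S)
    P = k + q
    n_moments = G * (P * (P + 3) // 2)
    n_free = G * (2 * k + q + q * (q + 1) // 2)
    return N * F, n_moments - n_free


def rmsea_value(chi2_val: float, df: int, n: int, n_groups: int = 1) -> float:
    """Point RMSEA: sqrt(G * max(chi2 - df, 0) / (df * N)); 0 when df = 0."""
    if df <= 0:
        return 0.0
    return float(np.sqrt(n_groups * max(chi2_val - df, 0.0) / (df * n)))


def cfi_tli(chi2_m: float, df_m: int, chi2_b: float, df_b: int) -> tuple[float, float]:
    """Comparative and Tucker-Lewis indices, clipped to [0, 1] for reporting."""
    dm = max(chi2_m - df_m, 0.0)
    db = max(chi2_b - df_b, dm, 0.0)
    cfi = 1.0 if db == 0 else 1.0 - dm / db
    if df_m > 0 and df_b > 0 and chi2_b / df_b > 1:
        tli = ((chi2_b / df_b) - (chi2_m / df_m)) / ((chi2_b / df_b) - 1.0)
    else:
        tli = 1.0
    return float(np.clip(cfi, 0.0, 1.0)), float(np.clip(tli, 0.0, 1.0))


def _rmsea_ci(chi2_val: float, df: int, N: int, G: int,
              level: float = 0.90) -> tuple[float, float]:
    if df <= 0:
        return (0.0, 0.0)
    lo_q = 0.5 + level / 2
    hi_q = 0.5 - level / 2

    def bound(prob):
        # find noncentrality nc with ncx2.cdf(chi2, df, nc) = prob
        if stats.chi2.cdf(chi2_val, df) < prob:
            return 0.0
        hi = max(chi2_val * 2, 10.0)
        while stats.ncx2.cdf(chi2_val, df, hi) > prob:
            hi *= 2
            if hi > 1e8:
                break
        return optimize.brentq(
            lambda nc: stats.ncx2.cdf(chi2_val, df, nc) - prob, 0.0, hi
        )

    nc_lo = bound(lo_q)
    nc_hi = bound(hi_q)
    return (float(np.sqrt(G * nc_lo / (df * N))),
            float(np.sqrt(G * nc_hi / (df * N))))


def fit_indices(fit: FactorFit) -> FitIndices:
    """CFI / TLI / RMSEA (with 90% CI) / SRMR against the independence baseline."""
    chi2_m, df_m = fit.chi2, fit.df
    N, G = fit.n, len(fit.group_names)
    if df_m == 0:
        return FitIndices(chi2=chi2_m, df=0, p_value=1.0, cfi=1.0, tli=1.0,
                          rmsea=0.0, rmsea_ci=(0.0, 0.0), srmr=fit.srmr())
    chi2_b, df_b = _baseline_chi2(fit)
    cfi, tli = cfi_tli(chi2_m, df_m, chi2_b, df_b)
    rmsea = rmsea_value(chi2_m, df_m, N, G)
    ci = _rmsea_ci(chi2_m, df_m, N, G)
    p = float(stats.chi2.sf(chi2_m, df_m))
    return FitIndices(chi2=float(chi2_m), df=int(df_m), p_value=p, cfi=cfi,
                      tli=tli, rmsea=rmsea, rmsea_ci=ci, srmr=fit.srmr())
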