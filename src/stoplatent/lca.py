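"""Latent class analysis of binary symptom items.

Finite-mixture model: subject i belongs to unobserved class k with
probability pi_k and endorses item j with class-conditional probability
rho_kj, items independent given class. Estimation is EM with multiple
random starts; the observed-data likelihood is computed over unique
response patterns (with counts) which makes enumeration over K and the
parametric-bootstrap likelihood-ratio test tractable at cohort sample
sizes. Missing items are handled by restricting each pattern's likelihood
to its observed entries.

Class enumeration mirrors the standard reporting ladder: AIC / BIC /
sample-size-adjusted BIC, relative entropy, Vuong-Lo-Mendell-Rubin and
Lo-Mendell-Rubin adjusted LRTs (chi-square approximations, labeled as
such), the parametric bootstrapped LRT, best-log-likelihood replication,
and a smallest-class-proportion floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

from ._utils import as_binary_matrix, check_rng

__all__ = [
    "LatentClassModel",
    "fit_lca",
    "information_criteria",
    "relative_entropy",
    "bootstrap_lrt",
    "lmr_lrt",
    "enumerate_classes",
    "select_model",
    "classify",
    "EnumerationReport",
]

_RHO_FLOOR = 1e-4  # keeps log(rho) finite at the parameter boundary


def _collapse_patterns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique response patterns, their counts, and the inverse index.

    NaN (missing) is treated as a third symbol so patterns with different
    missingness are kept distinct.
    """
    coded = np.where(np.isnan(X), 2, X).astype(np.int8)
    patterns, inverse, counts = np.unique(
        coded, axis=0, return_inverse=True, return_counts=True
    )
    return patterns, counts, inverse


def _pattern_loglik(patterns: np.ndarray, log_rho: np.ndarray,
                    log_1m_rho: np.ndarray) -> np.ndarray:
    """(n_patterns, K) matrix of log p(pattern | class)."""
    ones = (patterns == 1).astype(float)
    zeros = (patterns == 0).astype(float)
    return ones @ log_rho.T + zeros @ log_1m_rho.T


class LatentClassModel:
    """Binary-item latent class model fitted by multi-start EM.

    Parameters
    ----------
    n_classes : int
        Number of latent classes K (>= 1).
    n_starts : int
        Random EM starts; the best-log-likelihood solution is kept.
    tol : float
        Relative log-likelihood convergence tolerance per EM run.
    max_iter : int
        Iteration cap per EM run.
    random_state : int, Generator or None
        Seed for start values.

    Attributes (after ``fit``)
    --------------------------
    weights_ : (K,) class proportions pi_k.
    endorse_probs_ : (K, J) endorsement probabilities rho_kj.
    loglik_ : best observed-data log-likelihood.
    n_params_ : (K - 1) + K * J.
    converged_ : whether the best run met the tolerance.
    n_starts_at_best_ : number of starts reaching the best log-likelihood
        (within 1e-3); ``best_replicated_`` is True when >= 2.
    """

    def __init__(self, n_classes: int = 2, n_starts: int = 50, tol: float = 1e-6,
                 max_iter: int = 500, random_state=None):
        self.n_classes = n_classes
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_classes": self.n_classes, "n_starts": self.n_starts,
            "tol": self.tol, "max_iter": self.max_iter,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "LatentClassModel":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- EM machinery -------------------------------------------------------

    def _em_run(self, patterns, counts, pi0, rho0):
        n = counts.sum()
        pi = pi0.copy()
        rho = np.clip(rho0, _RHO_FLOOR, 1 - _RHO_FLOOR)
        observed = (patterns != 2)
        ones = (patterns == 1).astype(float)
        prev_ll = -np.inf
        converged = False
        for _ in range(self.max_iter):
            log_comp = (_pattern_loglik(patterns, np.log(rho), np.log1p(-rho))
                        + np.log(pi))
            ll_pat = logsumexp(log_comp, axis=1)
            ll = float(counts @ ll_pat)
            # EM ascent property; tiny slack for floating point
            if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
                raise AssertionError("EM log-likelihood decreased")
            resp = np.exp(log_comp - ll_pat[:, None])  # (P, K)
            w = resp * counts[:, None]
            class_mass = w.sum(axis=0)
            pi = np.maximum(class_mass / n, 1e-12)
            pi = pi / pi.sum()
            num = w.T @ ones                      # (K, J) endorsed mass
            den = w.T @ observed.astype(float)    # observed mass per item
            rho = np.clip(num / np.maximum(den, 1e-300),
                          _RHO_FLOOR, 1 - _RHO_FLOOR)
            if ll - prev_ll < self.tol * max(1.0, abs(ll)):
                prev_ll = ll
                converged = True
                break
            prev_ll = ll
        return prev_ll, pi, rho, converged

    def fit(self, X, y=None) -> "LatentClassModel":
        X = as_binary_matrix(X)
        n, J = X.shape
        K = self.n_classes
        if K < 1:
            raise ValueError("n_classes must be >= 1")
        patterns, counts, _ = _collapse_patterns(X)
        if K > patterns.shape[0]:
            import warnings
            warnings.warn(
                f"n_classes={K} exceeds the {patterns.shape[0]} distinct response "
                "patterns; the solution is degenerate", RuntimeWarning,
            )
        rng = check_rng(self.random_state)

        if K == 1:
            # closed form: independent Bernoulli items
            observed = (patterns != 2)
            ones = (patterns == 1).astype(float)
            rho = np.clip(
                (counts @ ones) / np.maximum(counts @ observed.astype(float), 1e-300),
                _RHO_FLOOR, 1 - _RHO_FLOOR,
            )[None, :]
            ll = float(counts @ _pattern_loglik(patterns, np.log(rho),
                                                np.log1p(-rho)).ravel())
            best = (ll, np.ones(1), rho, True)
            lls = [ll]
        else:
            best = None
            lls = []
            for _ in range(self.n_starts):
                pi0 = rng.dirichlet(np.ones(K))
                rho0 = rng.uniform(0.1, 0.9, size=(K, J))
                run = self._em_run(patterns, counts, pi0, rho0)
                lls.append(run[0])
                if best is None or run[0] > best[0]:
                    best = run

        self.loglik_, self.weights_, self.endorse_probs_, self.converged_ = best
        self.n_params_ = (K - 1) + K * J
        self.n_features_in_ = J
        self.n_obs_ = n
        self.n_starts_run_ = len(lls)
        self.n_starts_at_best_ = int(sum(abs(v - self.loglik_) < 1e-3 for v in lls))
        self.best_replicated_ = self.n_starts_at_best_ >= 2
        return self

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise RuntimeError("model is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class membership probabilities (rows sum to 1)."""
        self._check_fitted()
        X = as_binary_matrix(X)
        patterns, _, inverse = _collapse_patterns(X)
        log_comp = (_pattern_loglik(patterns, np.log(self.endorse_probs_),
                                    np.log1p(-self.endorse_probs_))
                    + np.log(self.weights_))
        post = np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])
        return post[inverse]

    def predict(self, X) -> np.ndarray:
        """Modal class assignment; ties break toward the lower class index."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None) -> float:
        """Total observed-data log-likelihood of ``X`` under the fitted model."""
        self._check_fitted()
        X = as_binary_matrix(X)
        patterns, counts, _ = _collapse_patterns(X)
        log_comp = (_pattern_loglik(patterns, np.log(self.endorse_probs_),
                                    np.log1p(-self.endorse_probs_))
                    + np.log(self.weights_))
        return float(counts @ logsumexp(log_comp, axis=1))

    def sample(self, n: int, rng=None) -> np.ndarray:
        """Parametric draw of ``n`` subjects from the fitted mixture."""
        self._check_fitted()
        rng = check_rng(rng)
        labels = rng.choice(self.n_classes, size=n, p=self.weights_)
        probs = self.endorse_probs_[labels]
        return (rng.random(probs.shape) < probs).astype(float)


def fit_lca(items, n_classes: int, n_starts: int = 50, seed=None,
            tol: float = 1e-6, max_iter: int = 500) -> LatentClassModel:
    """Functional wrapper over :class:`LatentClassModel`."""
    X = items.drop(columns="subject_id") if hasattr(items, "columns") and \
        "subject_id" in getattr(items, "columns", []) else items
    return LatentClassModel(
        n_classes=n_classes, n_starts=n_starts, tol=tol,
        max_iter=max_iter, random_state=seed,
    ).fit(X)


def information_criteria(loglik: float, n_params: int, n: int) -> tuple[float, float, float]:
    """(AIC, BIC, ABIC): -2LL + {2p, p ln n, p ln((n+2)/24)}."""
    if n <= 0:
        raise ValueError("n must be positive")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(n)
    abic = -2.0 * loglik + n_params * np.log((n + 2.0) / 24.0)
    return aic, bic, abic


def relative_entropy(posteriors: np.ndarray) -> float:
    """Normalized classification certainty in [0, 1].

    E = 1 - sum_i sum_k (-p_ik ln p_ik) / (n ln K); 1 for K = 1 by convention.
    """
    P = np.asarray(posteriors, float)
    n, K = P.shape
    if K == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(K)))


def classify(model: LatentClassModel, X) -> np.ndarray:
    """Modal class labels (argmax posterior, ties to the lower index)."""
    return model.predict(X)


def lmr_lrt(loglik_k: float, loglik_km1: float, n_params_k: int,
            n_params_km1: int, n: int) -> tuple[float, float]:
    """Approximate (VLMR p, LMR-adjusted p) for K-1 vs K classes.

    Uses a chi-square reference with df equal to the parameter-count
    difference; the adjusted statistic divides the LR by
    1 + 1/(df * ln n), a small-sample correction in the spirit of the
    original Lo-Mendell-Rubin proposal. Both p-values are approximations
    (the exact weighted-chi-square reference is not reproduced) and are
    flagged as approximate wherever reported.
    """
    lr = max(2.0 * (loglik_k - loglik_km1), 0.0)
    df = n_params_k - n_params_km1
    if df <= 0:
        raise ValueError("fits must be for adjacent, increasing K")
    if lr == 0.0:
        return 1.0, 1.0
    p_vlmr = float(chi2.sf(lr, df))
    lr_adj = lr / (1.0 + 1.0 / (df * np.log(n)))
    p_lmr = float(chi2.sf(lr_adj, df))
    return p_vlmr, p_lmr


def bootstrap_lrt(X, n_classes: int, n_boot: int = 50, seed=None,
                  n_starts: int = 20, tol: float = 1e-6) -> dict:
    """Parametric bootstrapped LRT of K-1 vs K classes.

    The observed statistic is -2(LL_{K-1} - LL_K). ``n_boot`` datasets are
    drawn from the (K-1)-class MLE and refitted at both K-1 and K; the
    p-value is (1 + #{boot stat >= observed}) / (n_boot + 1).
    """
    if n_classes < 2:
        raise ValueError("bootstrap LRT needs n_classes >= 2")
    X = as_binary_matrix(X)
    rng = check_rng(seed)
    n = X.shape[0]

    def _fit(data, K):
        return LatentClassModel(
            n_classes=K, n_starts=(1 if K == 1 else n_starts), tol=tol,
            random_state=rng,
        ).fit(data)

    null_fit = _fit(X, n_classes - 1)
    alt_fit = _fit(X, n_classes)
    observed = max(2.0 * (alt_fit.loglik_ - null_fit.loglik_), 0.0)

    boot_stats = np.empty(n_boot)
    n_restarted = 0
    for b in range(n_boot):
        Xb = null_fit.sample(n, rng=rng)
        fb0 = _fit(Xb, n_classes - 1)
        fb1 = _fit(Xb, n_classes)
        if not (fb0.converged_ and fb1.converged_):
            n_restarted += 1
            fb0 = _fit(Xb, n_classes - 1)
            fb1 = _fit(Xb, n_classes)
        boot_stats[b] = max(2.0 * (fb1.loglik_ - fb0.loglik_), 0.0)

    p = (1.0 + np.sum(boot_stats >= observed)) / (n_boot + 1.0)
    return {
        "statistic": observed,
        "p_value": float(p),
        "boot_stats": boot_stats,
        "n_boot": n_boot,
        "n_restarted": n_restarted,
        "fit_null": null_fit,
        "fit_alt": alt_fit,
    }


@dataclass
class EnumerationReport:
    """Per-K fit summary, criterion verdicts, and the selected class count."""

    table: pd.DataFrame
    verdicts: pd.DataFrame
    selected: int | None
    fits: dict[int, LatentClassModel] = field(default_factory=dict, repr=False)
    note: str = ""


def enumerate_classes(X, k_max: int = 5, n_starts: int = 50, n_boot: int = 50,
                      boot_starts: int = 20, seed=None,
                      alpha: float = 0.05) -> EnumerationReport:
    """Fit K = 1..k_max, compute the full reporting ladder, and select K.

    ``n_boot=0`` skips the parametric bootstrap (LRT criteria then rest on
    the VLMR/LMR approximations alone).
    """
    X = as_binary_matrix(np.asarray(
        X.drop(columns="subject_id") if hasattr(X, "columns") and
        "subject_id" in getattr(X, "columns", []) else X, dtype=float))
    n = X.shape[0]
    rng = check_rng(seed)
    fits: dict[int, LatentClassModel] = {}
    rows = []
    for K in range(1, k_max + 1):
        fit = LatentClassModel(n_classes=K, n_starts=n_starts,
                               random_state=rng).fit(X)
        fits[K] = fit
        aic, bic, abic = information_criteria(fit.loglik_, fit.n_params_, n)
        ent = relative_entropy(fit.predict_proba(X)) if K > 1 else np.nan
        row = {
            "K": K, "loglik": fit.loglik_, "n_params": fit.n_params_,
            "AIC": aic, "BIC": bic, "ABIC": abic, "entropy": ent,
            "smallest_class": float(fit.weights_.min()),
            "replicated": bool(fit.best_replicated_) if K > 1 else True,
            "VLMR_p": np.nan, "LMR_p": np.nan, "PB_p": np.nan,
        }
        if K > 1:
            row["VLMR_p"], row["LMR_p"] = lmr_lrt(
                fit.loglik_, fits[K - 1].loglik_, fit.n_params_,
                fits[K - 1].n_params_, n,
            )
            if n_boot > 0:
                row["PB_p"] = bootstrap_lrt(
                    X, K, n_boot=n_boot, seed=rng, n_starts=boot_starts
                )["p_value"]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("K")
    report = select_model(table, alpha=alpha)
    report.fits = fits
    return report


def select_model(table: pd.DataFrame, alpha: float = 0.05,
                 min_class_prop: float = 0.02,
                 min_entropy: float = 0.90) -> EnumerationReport:
    """Apply the five selection criteria to an enumeration table.

    Criteria per K (K >= 2): information criteria all decreased relative to
    K-1; relative entropy > 0.90; all available LRT p-values < alpha;
    smallest class proportion > 2%; best log-likelihood replicated. The
    selected K is the largest K passing all criteria whose successor fails
    at least one (the top of the fitted range counts as having no passing
    successor, noted in ``note``).
    """
    verdict_rows = []
    for K in table.index:
        if K == 1:
            verdict_rows.append({
                "K": K, "ic_decreased": True, "entropy_ok": True,
                "lrt_significant": True, "proportions_ok": True,
                "replicated": True, "passes_all": True,
            })
            continue
        prev = table.loc[K - 1]
        cur = table.loc[K]
        ic_dec = bool((cur[["AIC", "BIC", "ABIC"]].to_numpy()
                       < prev[["AIC", "BIC", "ABIC"]].to_numpy()).all())
        ent_ok = bool(cur["entropy"] > min_entropy)
        ps = [cur[c] for c in ("VLMR_p", "LMR_p", "PB_p") if np.isfinite(cur[c])]
        lrt_ok = bool(ps) and all(p < alpha for p in ps)
        prop_ok = bool(cur["smallest_class"] > min_class_prop)
        rep_ok = bool(cur["replicated"])
        verdict_rows.append({
            "K": K, "ic_decreased": ic_dec, "entropy_ok": ent_ok,
            "lrt_significant": lrt_ok, "proportions_ok": prop_ok,
            "replicated": rep_ok,
            "passes_all": ic_dec and ent_ok and lrt_ok and prop_ok and rep_ok,
        })
    verdicts = pd.DataFrame(verdict_rows).set_index("K")

    selected = None
    note = ""
    passing = [int(K) for K in verdicts.index if verdicts.loc[K, "passes_all"]]
    for K in sorted(passing, reverse=True):
        if K + 1 not in verdicts.index:
            selected = K
            note = "top of the fitted range passed all criteria"
            break
        if not verdicts.loc[K + 1, "passes_all"]:
            selected = K
            break
    if selected is None and passing:
        selected = max(passing)
    if not passing:
        note = "no class count passed all criteria"
    return EnumerationReport(table=table, verdicts=verdicts,
                             selected=selected, note=note)
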