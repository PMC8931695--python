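"""Exploratory factor analysis with oblique geomin rotation and the
Muthen-Muthen structure-discard criteria.

Maximum-likelihood factor extraction is delegated to
:class:`statsmodels.multivariate.factor.Factor`; the geomin rotation (the
common default for oblique EFA of neuroimaging indicator sets) is a
gradient-projection implementation written here because the statsmodels
rotation menu does not include it.

A candidate structure with ``r`` factors is discarded when any of the
following holds: (i) the r-th eigenvalue of the sample correlation matrix is
below 1; (ii) two or more indicators carry cross-loadings above 0.10 in
absolute value; (iv) any factor ends up with two or fewer indicators.
Indicators whose primary loading falls below 0.30 (criterion iii) are
dropped and the structure re-fitted before the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor import Factor

from ._utils import check_rng

__all__ = [
    "ExploratoryFactorAnalysis",
    "fit_efa",
    "efa_discard",
    "EFADiscardReport",
    "rotate_geomin_oblique",
]


def _geomin_objective(L: np.ndarray, eps: float):
    """Geomin criterion value and gradient for a pattern matrix."""
    m = L.shape[1]
    L2 = L**2 + eps
    pro = np.exp(np.log(L2).sum(axis=1) / m)
    Q = pro.sum()
    Gq = (2.0 / m) * (L / L2) * pro[:, None]
    return Q, Gq


def _gpa_oblique(A: np.ndarray, T0: np.ndarray, eps: float,
                 max_iter: int = 1000, tol: float = 1e-8):
    """Gradient-projection algorithm for oblique rotation (Jennrich-style)."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _geomin_objective(L, eps)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.sqrt((Gp**2).sum())
        if s < tol:
            break
        al *= 2
        for _ in range(30):
            X = T - al * Gp
            X = X / np.sqrt((X**2).sum(axis=0))
            try:
                Xi = np.linalg.inv(X)
            except np.linalg.LinAlgError:
                al /= 2
                continue
            Lt = A @ Xi.T
            ft, Gq_t = _geomin_objective(Lt, eps)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2
        T, f, L, Gq = X, ft, Lt, Gq_t
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    Phi = T.T @ T
    return L, Phi, f


def rotate_geomin_oblique(A: np.ndarray, eps: float = 0.01, n_starts: int = 10,
                          random_state=None):
    """Oblique geomin rotation of an unrotated loading matrix ``A``.

    Multiple random orthonormal starts guard against rotation local minima.
    Returns (pattern loadings, factor correlation matrix).
    """
    m = A.shape[1]
    if m == 1:
        return A.copy(), np.ones((1, 1))
    rng = check_rng(random_state)
    best = None
    starts = [np.eye(m)]
    for _ in range(n_starts - 1):
        M = rng.standard_normal((m, m))
        Q, _ = np.linalg.qr(M)
        starts.append(Q / np.sqrt((Q**2).sum(axis=0)))
    for T0 in starts:
        L, Phi, f = _gpa_oblique(A, T0, eps)
        if best is None or f < best[2]:
            best = (L, Phi, f)
    L, Phi, _ = best
    # sign convention: each factor's largest loading positive
    signs = np.sign(L[np.abs(L).argmax(axis=0), np.arange(m)])
    signs[signs == 0] = 1.0
    return L * signs, Phi * np.outer(signs, signs)


class ExploratoryFactorAnalysis:
    """ML exploratory factor analysis on the correlation scale.

    Attributes after ``fit``: ``loadings_`` (rotated pattern, DataFrame),
    ``phi_`` (factor correlations), ``eigenvalues_`` (of the sample
    correlation matrix), ``uniquenesses_``.
    """

    def __init__(self, n_factors: int = 1, rotation: str = "geomin",
                 geomin_eps: float = 0.01, random_state=None):
        self.n_factors = n_factors
        self.rotation = rotation
        self.geomin_eps = geomin_eps
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_factors": self.n_factors, "rotation": self.rotation,
                "geomin_eps": self.geomin_eps, "random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X) -> "ExploratoryFactorAnalysis":
        cols = list(X.columns) if hasattr(X, "columns") else [
            f"x{i}" for i in range(np.asarray(X).shape[1])
        ]
        arr = np.asarray(X[cols] if hasattr(X, "columns") else X, dtype=float)
        R = np.corrcoef(arr, rowvar=False)
        self.eigenvalues_ = np.sort(np.linalg.eigvalsh(R))[::-1]
        fac = Factor(arr, n_factor=self.n_factors, method="ml")
        res = fac.fit()
        A = np.asarray(res.loadings)[:, : self.n_factors]
        if self.n_factors == 1 or self.rotation is None:
            L, Phi = A.copy(), np.eye(self.n_factors)
            if self.n_factors == 1 and L.sum() < 0:
                L = -L
        elif self.rotation == "geomin":
            L, Phi = rotate_geomin_oblique(
                A, eps=self.geomin_eps, random_state=self.random_state
            )
        else:
            raise ValueError(f"unknown rotation {self.rotation!r}")
        self.loadings_ = pd.DataFrame(
            L, index=cols, columns=[f"f{j + 1}" for j in range(self.n_factors)]
        )
        self.phi_ = Phi
        self.uniquenesses_ = np.asarray(res.uniqueness)
        self.n_obs_ = arr.shape[0]
        return self


def fit_efa(betas, n_factors: int, rotation: str = "geomin",
            random_state=None) -> ExploratoryFactorAnalysis:
    """Functional wrapper over :class:`ExploratoryFactorAnalysis`."""
    if n_factors not in (1, 2, 3):
        raise ValueError("n_factors must be 1, 2 or 3")
    return ExploratoryFactorAnalysis(
        n_factors=n_factors, rotation=rotation, random_state=random_state
    ).fit(betas)


@dataclass
class EFADiscardReport:
    verdicts: pd.DataFrame
    retained_n_factors: int | None
    retained_structure: dict[str, list[str]] | None
    dropped_indicators: list[str]


def _evaluate_structure(efa: ExploratoryFactorAnalysis,
                        cross_threshold: float, loading_threshold: float,
                        min_indicators: int):
    L = efa.loadings_
    primary = L.abs().to_numpy().argmax(axis=1)
    weak = [L.index[i] for i in range(len(L))
            if abs(L.iloc[i, primary[i]]) < loading_threshold]
    cross_count = 0
    for i in range(len(L)):
        others = np.abs(np.delete(L.iloc[i].to_numpy(), primary[i]))
        if (others > cross_threshold).any():
            cross_count += 1
    assignment: dict[str, list[str]] = {c: [] for c in L.columns}
    for i, col in enumerate(L.columns[primary]):
        assignment[col].append(L.index[i])
    small_factor = any(len(v) <= min_indicators - 1 for v in assignment.values())
    return weak, cross_count, assignment, small_factor


def efa_discard(efa_results: dict[int, ExploratoryFactorAnalysis],
                data=None, cross_threshold: float = 0.10,
                loading_threshold: float = 0.30,
                min_indicators: int = 3) -> EFADiscardReport:
    """Apply the four structure-discard criteria and return the survivor.

    ``efa_results`` maps candidate factor counts to fitted EFAs (ideally
    1..3). Indicators failing the primary-loading floor (criterion iii) are
    dropped and the structure re-fitted on ``data`` when provided. Among
    admissible candidates the most granular (largest factor count) is
    retained; when none survives the report says so explicitly.
    """
    rows = []
    retained = None
    retained_struct = None
    dropped: list[str] = []
    for r in sorted(efa_results):
        efa = efa_results[r]
        eig_ok = bool(efa.eigenvalues_[r - 1] >= 1.0)
        weak, cross_count, assignment, small_factor = _evaluate_structure(
            efa, cross_threshold, loading_threshold, min_indicators
        )
        cur_dropped = list(weak)
        if weak:
            keep = [c for c in efa.loadings_.index if c not in weak]
            if data is not None and len(keep) >= r * min_indicators:
                # criterion (iii): drop the weak indicators, re-fit, re-evaluate
                refit = ExploratoryFactorAnalysis(
                    n_factors=r, rotation=efa.rotation,
                    geomin_eps=efa.geomin_eps, random_state=efa.random_state,
                ).fit(data[keep] if hasattr(data, "columns") else data)
                weak2, cross_count, assignment, small_factor = _evaluate_structure(
                    refit, cross_threshold, loading_threshold, min_indicators
                )
                cur_dropped += weak2
                weak = weak2
            else:
                # no data to re-fit: remove the weak indicators from the
                # assignment and re-check factor sizes on the remainder
                for v in assignment.values():
                    for w in weak:
                        if w in v:
                            v.remove(w)
                small_factor = any(
                    len(v) <= min_indicators - 1 for v in assignment.values()
                )
                weak = []
        cross_ok = cross_count < 2
        loading_ok = not weak
        size_ok = not small_factor
        passes = eig_ok and cross_ok and loading_ok and size_ok
        rows.append({
            "n_factors": r, "eigenvalue_ok": eig_ok,
            "cross_loadings_ok": cross_ok, "loadings_ok": loading_ok,
            "factor_size_ok": size_ok, "passes": passes,
        })
        if passes:
            retained = r
            retained_struct = {k: v for k, v in assignment.items() if v}
            dropped = cur_dropped
    verdicts = pd.DataFrame(rows).set_index("n_factors")
    return EFADiscardReport(
        verdicts=verdicts, retained_n_factors=retained,
        retained_structure=retained_struct, dropped_indicators=dropped,
    )
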