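"""CFA: closed-form oracles, recovery at published loadings, fit indices,
tetrachoric/binary-item path."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from stoplatent import (FactorModelSpec, cfi_tli, fit_cfa, fit_cfa_binary,
                        fit_indices, rmsea_value, tetrachoric_pair)
from stoplatent.cfa import ConfirmatoryFactorAnalysis


def exact_cov_data(target_cov, n=60, seed=0):
    """Data whose biased sample covariance equals ``target_cov`` exactly."""
    rng = np.random.default_rng(seed)
    k = target_cov.shape[0]
    Z = rng.standard_normal((n, k))
    Z -= Z.mean(axis=0)
    S = np.cov(Z, rowvar=False, bias=True)
    W = np.linalg.cholesky(np.linalg.inv(S))
    return (Z @ W) @ np.linalg.cholesky(target_cov).T


class TestTriadOracle:
    def test_just_identified_triad_matches_closed_form(self):
        # sigma12=.56, sigma13=.48, sigma23=.42 -> lambda = (0.8, 0.7, 0.6)
        S = np.array([[1.0, 0.56, 0.48],
                      [0.56, 1.0, 0.42],
                      [0.48, 0.42, 1.0]])
        Y = pd.DataFrame(exact_cov_data(S), columns=["a", "b", "c"])
        spec = FactorModelSpec(factors={"f": ["a", "b", "c"]})
        fit = fit_cfa(spec, Y)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-4)
        lam1 = np.sqrt(0.56 * 0.48 / 0.42)
        std = fit.standardized_loadings().to_numpy().ravel()
        assert std == pytest.approx([lam1, 0.7, 0.6], abs=1e-3)
        idx = fit_indices(fit)
        assert idx.rmsea == 0.0 and idx.cfi == 1.0


class TestRecovery:
    def test_published_response_inhibition_loadings_recovered(self, ri_betas_5k):
        betas, cfg = ri_betas_5k
        spec = FactorModelSpec(factors={
            "ri": cfg.factor_blocks[0].indicators
        })
        fit = fit_cfa(spec, betas)
        std = fit.standardized_loadings().to_numpy().ravel()
        assert np.all(np.abs(std - [0.91, 0.86, 0.68, 0.51]) < 0.03)

    def test_zero_uniqueness_flags_heywood_adjacent_solution(self):
        rng = np.random.default_rng(4)
        eta = rng.standard_normal(400)
        lam = np.array([0.8, 0.7, 0.6])
        Y = pd.DataFrame(eta[:, None] * lam[None, :],
                         columns=["a", "b", "c"])
        Y += rng.standard_normal(Y.shape) * 0.02
        spec = FactorModelSpec(factors={"f": ["a", "b", "c"]})
        fit = fit_cfa(spec, Y)
        std = np.abs(fit.standardized_loadings().to_numpy().ravel())
        assert np.all(std > 0.99)
        assert np.all(fit.uniquenesses[0] < 0.01)

    def test_mimic_covariate_effect_estimated(self):
        rng = np.random.default_rng(8)
        n = 4000
        x = rng.standard_normal(n)
        eta = 0.5 * x + rng.standard_normal(n)
        lam = np.array([0.9, 0.8, 0.7])
        Y = pd.DataFrame(
            eta[:, None] * lam[None, :]
            + rng.standard_normal((n, 3)) * np.sqrt(1 - lam**2),
            columns=["a", "b", "c"],
        )
        X = pd.DataFrame({"x": x})
        spec = FactorModelSpec(factors={"f": ["a", "b", "c"]},
                               covariates=("x",))
        fit = fit_cfa(spec, Y, covariates=X)
        # gamma in anchor units: anchor loading 0.9 -> 0.9 * 0.5 = 0.45
        assert fit.gamma[0][0, 0] == pytest.approx(0.45, abs=0.05)


class TestModelProperties:
    def _two_group_data(self, seed=3, n=400):
        rng = np.random.default_rng(seed)
        lam = np.array([0.9, 0.8, 0.7, 0.6])
        rows, groups = [], []
        for g in range(2):
            eta = rng.standard_normal(n)
            Y = eta[:, None] * lam + rng.standard_normal((n, 4)) * 0.5
            rows.append(Y)
            groups += [g] * n
        return (pd.DataFrame(np.vstack(rows), columns=list("abcd")),
                np.array(groups))

    def test_freeing_parameters_never_lowers_loglik(self):
        Y, groups = self._two_group_data()
        spec = FactorModelSpec(factors={"f": list("abcd")})
        lls = {}
        for level in ("scalar", "metric", "configural"):
            est = ConfirmatoryFactorAnalysis(spec, level=level)
            est.fit(Y, groups=groups)
            lls[level] = est.fit_.loglik
        assert lls["configural"] >= lls["metric"] - 1e-4
        assert lls["metric"] >= lls["scalar"] - 1e-4

    def test_standardized_solution_invariant_to_indicator_rescaling(self):
        Y, _ = self._two_group_data(seed=9)
        spec = FactorModelSpec(factors={"f": list("abcd")})
        fit1 = fit_cfa(spec, Y)
        Y2 = Y.copy()
        Y2["b"] = Y2["b"] * 3.7
        fit2 = fit_cfa(spec, Y2)
        np.testing.assert_allclose(
            fit1.standardized_loadings().to_numpy(),
            fit2.standardized_loadings().to_numpy(), atol=1e-4,
        )

    def test_implied_covariance_symmetric_psd_at_optimum(self):
        Y, _ = self._two_group_data(seed=11)
        spec = FactorModelSpec(factors={"f": list("abcd")})
        fit = fit_cfa(spec, Y)
        Sigma = fit.implied_cov()
        assert np.allclose(Sigma, Sigma.T)
        assert np.linalg.eigvalsh(Sigma).min() > 0

    def test_ml_solution_matches_derivative_free_optimizer_oracle(self):
        Y, _ = self._two_group_data(seed=13, n=300)
        spec = FactorModelSpec(factors={"f": list("abcd")})
        est = ConfirmatoryFactorAnalysis(spec)
        est.fit(Y)
        fit = est.fit_
        layout = fit.layout
        y = Y.to_numpy()
        S = np.cov(y, rowvar=False, bias=True)
        sign, logdet_S = np.linalg.slogdet(S)
        sample = [{"n": len(y), "S": S, "mbar": y.mean(axis=0),
                   "logdet_S": logdet_S, "P": 4,
                   "xmom": (np.zeros((0, 0)), np.zeros(0))}]
        res = optimize.minimize(
            est._discrepancy, fit.theta_free + 0.05, args=(layout, sample),
            method="Nelder-Mead",
            options={"maxiter": 60000, "maxfev": 60000,
                     "xatol": 1e-9, "fatol": 1e-12},
        )
        n = len(y)
        # F-difference of 2*eps/n corresponds to loglik difference eps
        assert fit.f_min <= res.fun + 2e-4 / n
        assert abs(fit.f_min - res.fun) * n / 2 < 1e-4


class TestFitIndices:
    def test_rmsea_formula_hand_case(self):
        assert rmsea_value(50.0, 25, 100) == pytest.approx(0.10)

    def test_perfect_fit_gives_zero_rmsea_unit_cfi(self):
        cfi, tli = cfi_tli(25.0, 25, 500.0, 30)
        assert cfi == 1.0
        assert rmsea_value(25.0, 25, 100) == 0.0

    def test_saturated_model_has_zero_srmr(self):
        S = np.array([[1.0, 0.56, 0.48],
                      [0.56, 1.0, 0.42],
                      [0.48, 0.42, 1.0]])
        Y = pd.DataFrame(exact_cov_data(S), columns=["a", "b", "c"])
        spec = FactorModelSpec(factors={"f": ["a", "b", "c"]})
        fit = fit_cfa(spec, Y)  # just-identified: reproduces S exactly
        assert fit.srmr() == pytest.approx(0.0, abs=1e-5)

    def test_rmsea_ci_brackets_point_estimate(self, ri_betas_5k):
        betas, cfg = ri_betas_5k
        spec = FactorModelSpec(factors={"ri": cfg.factor_blocks[0].indicators})
        idx = fit_indices(fit_cfa(spec, betas))
        lo, hi = idx.rmsea_ci
        assert lo <= idx.rmsea <= hi


class TestBinaryItems:
    def test_tetrachoric_matches_bivariate_normal_oracle(self):
        # cells from rho = 0.6 with both thresholds at 0:
        # P11 = 1/4 + arcsin(rho) / (2 pi)
        p11 = 0.25 + np.arcsin(0.6) / (2 * np.pi)
        n = 10_000
        n11 = round(p11 * n)
        n10 = n01 = round((0.5 - p11) * n)
        n00 = n - n11 - n10 - n01
        x = np.concatenate([np.ones(n11), np.ones(n10),
                            np.zeros(n01), np.zeros(n00)])
        y = np.concatenate([np.ones(n11), np.zeros(n10),
                            np.ones(n01), np.zeros(n00)])
        rho, flagged = tetrachoric_pair(x, y)
        assert not flagged
        assert rho == pytest.approx(0.60, abs=0.02)

    def test_identical_columns_capped_and_flagged(self):
        # empty discordant cells trigger the continuity correction, which
        # pulls the estimate just below the boundary; the pair is flagged
        x = np.array([0, 0, 1, 1, 0, 1, 1, 0, 1, 0], float)
        rho, flagged = tetrachoric_pair(x, x)
        assert flagged
        assert rho > 0.95

    def test_threshold_model_loadings_recovered(self):
        rng = np.random.default_rng(17)
        n = 20_000
        lam = 0.7
        eta = rng.standard_normal(n)
        z = lam * eta[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, 4))
        items = pd.DataFrame((z > 0).astype(float),
                             columns=["i1", "i2", "i3", "i4"])
        spec = FactorModelSpec(factors={"f": ["i1", "i2", "i3", "i4"]})
        fit = fit_cfa_binary(items, spec)
        assert np.all(np.abs(fit.loadings.to_numpy().ravel() - 0.7) < 0.05)
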