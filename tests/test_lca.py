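"""Latent class analysis: EM correctness, criteria arithmetic, LRTs, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit, logit

from stoplatent import (LatentClassModel, PhenotypeGenConfig, bootstrap_lrt,
                        classify, generate_symptoms, information_criteria,
                        lmr_lrt, relative_entropy, select_model)
from stoplatent._utils import align_permutation


def _mixture_loglik(counts, patterns, pi, rho):
    """Direct mixture log-likelihood over pattern counts (oracle arithmetic)."""
    like = np.zeros(len(patterns))
    for k in range(len(pi)):
        pk = np.prod(np.where(patterns == 1, rho[k], 1 - rho[k]), axis=1)
        like += pi[k] * pk
    return float(counts @ np.log(like))


class TestEMFit:
    def test_one_class_closed_form_matches_bernoulli_likelihood(self, rng):
        X = (rng.random((200, 5)) < 0.3).astype(float)
        fit = LatentClassModel(n_classes=1).fit(X)
        means = X.mean(axis=0)
        assert np.allclose(fit.endorse_probs_.ravel(), means, atol=1e-3)
        ll = np.sum(X * np.log(fit.endorse_probs_)
                    + (1 - X) * np.log(1 - fit.endorse_probs_))
        assert abs(fit.loglik_ - ll) < 1e-8

    def test_two_class_solution_matches_independent_optimizer_oracle(self):
        # 3-item toy with fixed pattern counts; the oracle is a coarse grid
        # over (rho, pi) refined by Nelder-Mead on the same likelihood,
        # fully independent of the EM iteration path.
        rng = np.random.default_rng(12)
        true_rho = np.array([[0.9, 0.8, 0.7], [0.2, 0.1, 0.3]])
        lab = rng.choice(2, size=20, p=[0.5, 0.5])
        X = (rng.random((20, 3)) < true_rho[lab]).astype(float)
        patterns, counts = np.unique(X, axis=0, return_counts=True)

        grid = np.arange(0.05, 1.0, 0.1)
        pis = np.arange(0.1, 0.91, 0.1)
        triples = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
        # P[g, s] = prob of pattern s under rho-triple g (vectorized grid)
        P = np.prod(
            np.where(patterns[None, :, :] == 1,
                     triples[:, None, :], 1 - triples[:, None, :]),
            axis=2,
        )
        best = (-np.inf, None)
        for pi1 in pis:
            mix = pi1 * P[:, None, :] + (1 - pi1) * P[None, :, :]
            ll_all = np.log(mix) @ counts
            idx = np.unravel_index(np.argmax(ll_all), ll_all.shape)
            if ll_all[idx] > best[0]:
                best = (float(ll_all[idx]),
                        (pi1, np.array([triples[idx[0]], triples[idx[1]]])))

        def neg_ll(t):
            pi1 = expit(t[0])
            rho = expit(t[1:]).reshape(2, 3)
            return -_mixture_loglik(counts, patterns,
                                    np.array([pi1, 1 - pi1]), rho)

        pi1_0, rho_0 = best[1]
        t0 = np.concatenate([[logit(pi1_0)], logit(rho_0.ravel())])
        res = minimize(neg_ll, t0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10,
                                "fatol": 1e-12})
        oracle_ll = -res.fun

        fit = LatentClassModel(n_classes=2, n_starts=50,
                               random_state=0).fit(X)
        assert abs(fit.loglik_ - oracle_ll) < 1e-3

    def test_four_class_recovery_of_default_mixing_proportions(
        self, default_symptoms_10k
    ):
        table, labels, cfg = default_symptoms_10k
        X = table.drop(columns="subject_id")
        fit = LatentClassModel(n_classes=4, n_starts=30,
                               random_state=5).fit(X)
        perm = align_permutation(np.asarray(cfg.endorse_probs),
                                 fit.endorse_probs_)
        recovered = fit.weights_[perm]
        assert np.all(np.abs(recovered - cfg.class_proportions) < 0.005)

    def test_modal_labels_agree_with_truth_after_alignment(
        self, default_symptoms_10k
    ):
        table, labels, cfg = default_symptoms_10k
        X = table.drop(columns="subject_id")
        fit = LatentClassModel(n_classes=4, n_starts=30,
                               random_state=5).fit(X)
        perm = align_permutation(np.asarray(cfg.endorse_probs),
                                 fit.endorse_probs_)
        inv = np.argsort(perm)
        pred = inv[classify(fit, X)]
        assert (pred == labels).mean() >= 0.95

    def test_missing_items_handled_by_observed_likelihood(self, rng):
        cfg = PhenotypeGenConfig(seed=3)
        table, _ = generate_symptoms(cfg, 1500)
        X = table.drop(columns="subject_id").to_numpy(float)
        mask = rng.random(X.shape) < 0.1
        X[mask] = np.nan
        fit = LatentClassModel(n_classes=4, n_starts=10, random_state=1).fit(X)
        assert np.isfinite(fit.loglik_)
        post = fit.predict_proba(X)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            LatentClassModel(n_classes=2).fit(np.array([[0, 2.0], [1, 0]]))

    def test_posterior_tie_breaks_to_lower_class_index(self):
        m = LatentClassModel(n_classes=2)
        m.weights_ = np.array([0.5, 0.5])
        m.endorse_probs_ = np.array([[0.4], [0.4]])
        assert m.predict(np.array([[1.0]]))[0] == 0


class TestInformationCriteria:
    def test_zero_case(self):
        assert information_criteria(0.0, 0, 100) == (0.0, 0.0, 0.0)

    def test_hand_values(self):
        aic, bic, abic = information_criteria(-100.0, 5, 100)
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(200 + 5 * np.log(100), abs=1e-6)
        assert abic == pytest.approx(200 + 5 * np.log(102 / 24), abs=1e-6)

    @given(st.integers(1, 50), st.integers(2, 10_000),
           st.floats(-1e5, -1.0))
    @settings(max_examples=50, deadline=None)
    def test_aic_below_bic_iff_n_exceeds_e_squared(self, p, n, ll):
        aic, bic, _ = information_criteria(ll, p, n)
        assert (aic < bic) == (n > np.e**2)


class TestRelativeEntropy:
    def test_uniform_posteriors_give_zero(self):
        P = np.full((10, 4), 0.25)
        assert relative_entropy(P) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_posteriors_give_one(self):
        P = np.eye(4)[np.array([0, 1, 2, 3, 0])]
        assert relative_entropy(P) == pytest.approx(1.0)

    def test_hand_case_half(self):
        P = np.array([[0.5, 0.5], [1.0, 0.0]])
        assert relative_entropy(P) == pytest.approx(0.5)


class TestLRTs:
    def test_identical_logliks_give_p_one(self):
        assert lmr_lrt(-50.0, -50.0, 10, 5, 200) == (1.0, 1.0)

    def test_larger_ll_gap_gives_smaller_p(self):
        p1 = lmr_lrt(-45.0, -50.0, 10, 5, 200)[0]
        p2 = lmr_lrt(-40.0, -50.0, 10, 5, 200)[0]
        assert p2 < p1

    def test_adjusted_p_exceeds_vlmr_p(self):
        # the small-sample adjustment shrinks the statistic slightly
        vlmr, lmr = lmr_lrt(-40.0, -50.0, 10, 5, 200)
        assert lmr > vlmr

    def test_bootstrap_p_within_admissible_range(self, rng):
        X = (rng.random((150, 4)) < 0.4).astype(float)
        out = bootstrap_lrt(X, 2, n_boot=9, seed=1, n_starts=3)
        assert 1 / 10 <= out["p_value"] <= 1.0

    def test_bootstrap_detects_well_separated_two_class_structure(self):
        rng = np.random.default_rng(21)
        rho = np.array([[0.9, 0.9, 0.9, 0.9, 0.9], [0.1, 0.1, 0.1, 0.1, 0.1]])
        lab = rng.choice(2, size=2000)
        X = (rng.random((2000, 5)) < rho[lab]).astype(float)
        out = bootstrap_lrt(X, 2, n_boot=50, seed=2, n_starts=10)
        assert out["p_value"] <= 0.02

    def test_lmr_and_bootstrap_decisions_concordant(self):
        # clear null (1 class) and clear alternative (2 classes): the
        # chi-square approximation and the parametric bootstrap should
        # agree on accept/reject at alpha = .05 in >= 90% of datasets
        rng = np.random.default_rng(31)
        agree = total = 0
        for rep in range(30):
            if rep < 15:
                X = (rng.random((300, 5)) < 0.35).astype(float)
            else:
                rho = np.array([[0.85] * 5, [0.15] * 5])
                lab = rng.choice(2, size=300)
                X = (rng.random((300, 5)) < rho[lab]).astype(float)
            out = bootstrap_lrt(X, 2, n_boot=19, seed=rng, n_starts=5)
            f1, f2 = out["fit_null"], out["fit_alt"]
            p_lmr = lmr_lrt(f2.loglik_, f1.loglik_, f2.n_params_,
                            f1.n_params_, 300)[1]
            # bootstrap p-values are discrete with minimum 1/(B+1); the
            # rejection rule is p <= alpha
            agree += (p_lmr <= 0.05) == (out["p_value"] <= 0.05)
            total += 1
        assert agree / total >= 0.9


class TestSelection:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows).set_index("K")

    def _row(self, K, aic, ent=0.97, p=0.001, smallest=0.1, rep=True):
        return {"K": K, "AIC": aic, "BIC": aic + 50, "ABIC": aic + 20,
                "entropy": ent if K > 1 else np.nan,
                "VLMR_p": p if K > 1 else np.nan,
                "LMR_p": p if K > 1 else np.nan,
                "PB_p": p if K > 1 else np.nan,
                "smallest_class": smallest, "replicated": rep}

    def test_selects_four_when_five_fails_bootstrap_significance(self):
        rows = [self._row(1, 1000), self._row(2, 800), self._row(3, 700),
                self._row(4, 650)]
        rows.append(self._row(5, 640, p=0.2))
        report = select_model(self._table(rows))
        assert report.selected == 4
        assert not report.verdicts.loc[5, "lrt_significant"]

    def test_single_one_class_entry_selects_one(self):
        report = select_model(self._table([self._row(1, 1000)]))
        assert report.selected == 1

    def test_small_class_proportion_fails_two_percent_floor(self):
        rows = [self._row(1, 1000), self._row(2, 800),
                self._row(3, 700, smallest=0.015)]
        report = select_model(self._table(rows))
        assert not report.verdicts.loc[3, "proportions_ok"]
        assert report.selected == 2

    def test_no_passing_k_reports_none_with_diagnostics(self):
        rows = [self._row(1, 1000), self._row(2, 800, ent=0.5)]
        rows[0]["AIC"] = 500  # make K=2 fail the IC decrease too
        report = select_model(self._table(rows))
        # K=1 passes vacuously and has a failing successor -> selected 1
        assert report.selected == 1
        assert not report.verdicts.loc[2, "passes_all"]
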