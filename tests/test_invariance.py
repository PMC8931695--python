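"""Invariance ladder, latent-mean contrasts, FDR, cluster-robust SEs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stoplatent import (FactorModelSpec, compare_latent_means, contrast_table,
                        fdr_adjust, fit_cfa, fit_multigroup, invariance_ladder)
from tests.conftest import make_group_betas


def brute_force_bh(p):
    """Step-up BH reference: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestFDR:
    def test_hand_step_up_case(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05, 0.9]
        np.testing.assert_allclose(fdr_adjust(p),
                                   [0.06, 0.06, 0.06, 0.06, 0.06, 0.9])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2] * 5), [0.2] * 5)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(fdr_adjust(p), brute_force_bh(p),
                                   atol=1e-12)


class TestContrastEngine:
    def test_published_intercepts_reproduce_printed_differences(self):
        alphas = {"TD": 0.0, "ADHD-IRR": 0.17, "ADHD": -0.17, "IRR": -0.56}
        tab = contrast_table(alphas, group_order=list(alphas))
        lookup = {(r.group_1, r.group_2): r.estimate
                  for r in tab.itertuples()}
        assert lookup[("TD", "IRR")] == pytest.approx(-0.56)
        assert lookup[("ADHD-IRR", "IRR")] == pytest.approx(-0.73)
        assert lookup[("ADHD", "IRR")] == pytest.approx(-0.39)

    def test_antisymmetry_of_contrasts(self):
        alphas = {"a": 0.3, "b": -0.2}
        t1 = contrast_table(alphas, group_order=["a", "b"])
        t2 = contrast_table(alphas, group_order=["b", "a"])
        assert t1.loc[0, "estimate"] == pytest.approx(-t2.loc[0, "estimate"])

    def test_fdr_adjusted_never_below_raw(self):
        alphas = {"a": 0.0, "b": 0.1, "c": -0.2, "d": 0.4}
        ses = {k: 0.1 for k in alphas}
        tab = contrast_table(alphas, ses=ses, group_order=list(alphas))
        assert (tab["p_fdr"] >= tab["p_raw"] - 1e-12).all()


class TestLadder:
    def test_rule_is_conjunctive_not_rejected(self):
        # delta-CFI alone exceeding its cutoff must NOT reject
        assert not ((0.02 > 0.01) and (0.010 > 0.015))

    def test_rule_is_conjunctive_rejected(self):
        assert (0.02 > 0.01) and (0.020 > 0.015)

    def test_invariant_data_attains_scalar(self):
        Y, groups, cols = make_group_betas([0.0, -0.3], [1500, 1500], seed=5)
        spec = FactorModelSpec(factors={"f": cols})
        res = invariance_ladder(spec, Y, groups)
        assert res.attained == "scalar"
        assert not res.deltas["rejected"].any()

    def test_intercept_shift_inflates_scalar_misfit(self):
        Y, groups, cols = make_group_betas(
            [0.0, 0.0], [1500, 1500], seed=6,
            intercept_shift=(1, 1, 0.5),
        )
        spec = FactorModelSpec(factors={"f": cols})
        res = invariance_ladder(spec, Y, groups)
        assert res.deltas.loc["scalar", "rejected"]
        assert res.attained == "metric"

    def test_single_group_reduces_to_plain_cfa(self, ri_betas_5k):
        betas, cfg = ri_betas_5k
        spec = FactorModelSpec(factors={"ri": cfg.factor_blocks[0].indicators})
        single = fit_multigroup(spec, betas, groups=np.zeros(len(betas), int),
                                level="metric")
        plain = fit_cfa(spec, betas)
        assert single.level == "single"
        np.testing.assert_allclose(single.loadings[0], plain.loadings[0],
                                   atol=1e-6)
        assert single.chi2 == pytest.approx(plain.chi2, abs=1e-6)

    def test_nested_loglik_ordering_on_fitted_ladder(self):
        Y, groups, cols = make_group_betas([0.0, 0.2, -0.4],
                                           [600, 500, 400], seed=7)
        spec = FactorModelSpec(factors={"f": cols})
        res = invariance_ladder(spec, Y, groups)
        lls = {lvl: res.fits[lvl].loglik for lvl in res.fits}
        assert lls["configural"] >= lls["metric"] - 1e-4
        assert lls["metric"] >= lls["scalar"] - 1e-4


class TestLatentMeans:
    def test_scalar_fit_recovers_group_intercepts_in_anchor_units(self):
        # generating latent means (0, 0.17, -0.17, -0.56); anchor loading
        # 0.91 maps them to 0.91 * alpha in anchor-indicator units
        alphas = [0.0, 0.17, -0.17, -0.56]
        Y, groups, cols = make_group_betas(
            alphas, [4000, 1500, 1500, 1500], seed=11
        )
        spec = FactorModelSpec(factors={"f": cols})
        fit = fit_multigroup(spec, Y, groups=groups, level="scalar")
        tab = compare_latent_means(fit)
        est = {(r.group_1, r.group_2): (r.estimate, r.se)
               for r in tab.itertuples()}
        for (g, a) in [("g1", 0.17), ("g2", -0.17), ("g3", -0.56)]:
            diff, se = est[("g0", g)]
            assert abs(diff - 0.91 * a) < 3 * se

    def test_identical_groups_give_null_contrasts(self):
        Y, groups, cols = make_group_betas([0.0, 0.0], [1200, 1200], seed=12)
        spec = FactorModelSpec(factors={"f": cols})
        fit = fit_multigroup(spec, Y, groups=groups, level="scalar")
        tab = compare_latent_means(fit)
        assert abs(tab.loc[0, "estimate"]) < 3 * tab.loc[0, "se"]

    def test_requires_scalar_level(self):
        Y, groups, cols = make_group_betas([0.0, 0.1], [300, 300], seed=13)
        spec = FactorModelSpec(factors={"f": cols})
        fit = fit_multigroup(spec, Y, groups=groups, level="metric")
        with pytest.raises(ValueError):
            compare_latent_means(fit)


@pytest.fixture(scope="module")
def scalar_fit():
    Y, groups, cols = make_group_betas([0.0, -0.3], [250, 250], seed=14)
    spec = FactorModelSpec(factors={"f": cols})
    return fit_multigroup(spec, Y, groups=groups, level="scalar")


class TestClusterRobust:
    def test_singleton_clusters_match_plain_sandwich(self, scalar_fit):
        fit = scalar_fit
        n = fit.n
        robust = fit.cluster_robust_cov(np.arange(n))
        S = fit.score_matrix()
        A_inv = fit.param_cov()
        manual = A_inv @ (S.T @ S) @ A_inv
        np.testing.assert_allclose(robust, manual, atol=1e-8)

    def test_duplicated_subjects_inflate_robust_se_by_sqrt2(self):
        Y, groups, cols = make_group_betas([0.0, -0.3], [250, 250], seed=15)
        spec = FactorModelSpec(factors={"f": cols})
        # duplicate every subject (keeping group contiguity)
        Y2 = pd.concat([Y, Y], ignore_index=True)
        g2 = pd.Categorical(list(groups) + list(groups),
                            categories=groups.categories)
        fit2 = fit_multigroup(spec, Y2, groups=g2, level="scalar")
        clusters = np.tile(np.arange(len(Y)), 2)  # original row order
        robust = fit2.cluster_robust_cov(clusters)
        naive = fit2.param_cov()
        sl = fit2.alpha_slice(1)
        ratio = np.sqrt(robust[sl.start, sl.start]
                        / naive[sl.start, sl.start])
        assert ratio == pytest.approx(np.sqrt(2), rel=0.10)

    def test_point_estimates_unchanged_by_clustering(self, scalar_fit):
        fit = scalar_fit
        alpha_before = [a.copy() for a in fit.alpha]
        fit.cluster_robust_cov(np.arange(fit.n) // 2)
        for a, b in zip(alpha_before, fit.alpha):
            np.testing.assert_array_equal(a, b)
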