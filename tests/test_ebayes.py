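import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from genelm.datamodel import DesignSpec, FDistPrior
from genelm.ebayes import (decide_tests, fit_fdist, fit_fdist_robust,
                           moderated_stats, p_adjust, prop_true_null,
                           squeeze_var, top_table, treat, trigamma_inverse)
from genelm.linmod import contrasts_fit, lm_fit
from genelm.simulate import sim_log_matrix


class TestTrigammaInverse:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 50.0))
    def test_inverts_trigamma(self, x):
        y = float(special.polygamma(1, x))
        back = float(trigamma_inverse(y)[0])
        assert abs(back - x) / x < 1e-6


class TestFitFdist:
    def test_identical_variances_give_infinite_prior_df(self):
        s2 = np.full(100, 0.3)
        prior = fit_fdist(s2, 6.0)
        assert np.isinf(prior.df_prior)
        assert abs(prior.s2_prior - 0.3) / 0.3 < 1e-10

    def test_hyperparameter_recovery(self):
        # sigma2 ~ s0^2 d0 / chi2(d0), s2 | sigma2 ~ sigma2 chi2(df)/df
        rng = np.random.default_rng(20)
        d0, s0, df = 4.0, 0.05, 6.0
        sigma2 = s0 * d0 / rng.chisquare(d0, 20000)
        s2 = sigma2 * rng.chisquare(df, 20000) / df
        prior = fit_fdist(s2, df)
        assert abs(prior.df_prior - d0) / d0 < 0.15
        assert abs(prior.s2_prior - s0) / s0 < 0.05

    def test_zero_df_genes_excluded(self):
        rng = np.random.default_rng(21)
        s2 = rng.chisquare(6, 500) / 6
        df = np.full(500, 6.0)
        prior_full = fit_fdist(s2, df)
        s2x = np.concatenate([s2, [np.nan, 5.0]])
        dfx = np.concatenate([df, [0.0, 0.0]])
        prior_x = fit_fdist(s2x, dfx)
        assert prior_x.df_prior == pytest.approx(prior_full.df_prior)
        assert prior_x.s2_prior == pytest.approx(prior_full.s2_prior)

    def test_trended_prior_tracks_covariate(self):
        rng = np.random.default_rng(22)
        A = rng.uniform(4, 14, 5000)
        true = 0.05 * (0.5 + 2 * np.exp(-(A - 4) / 2))
        s2 = true * rng.chisquare(6, 5000) / 6
        prior = fit_fdist(s2, 6.0, covariate=A)
        assert prior.trended
        lowA = prior.s2_prior[A < 6].mean()
        highA = prior.s2_prior[A > 12].mean()
        assert lowA > 1.5 * highA   # prior follows the decreasing trend


class TestSqueezeVar:
    def test_posterior_formula(self):
        out = squeeze_var(np.array([2.0]), np.array([4.0]), FDistPrior(4.0, 1.0))
        assert out[0] == pytest.approx(1.5)   # (4*1 + 4*2) / 8

    def test_no_shrinkage_limit(self):
        s2 = np.array([0.5, 2.0, 7.0])
        out = squeeze_var(s2, np.array([4.0, 4.0, 4.0]), FDistPrior(0.0, 1.0))
        np.testing.assert_allclose(out, s2)

    def test_complete_shrinkage_limit(self):
        out = squeeze_var(np.array([0.5, 2.0]), np.array([4.0, 4.0]),
                          FDistPrior(np.inf, 1.3))
        np.testing.assert_allclose(out, 1.3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0), st.floats(0.1, 50.0), st.floats(0.1, 50.0))
    def test_between_prior_and_observed(self, s2, d0, df):
        out = squeeze_var(np.array([s2]), np.array([df]), FDistPrior(d0, 1.0))[0]
        assert min(s2, 1.0) - 1e-12 <= out <= max(s2, 1.0) + 1e-12


class TestModeratedStats:
    def test_zero_prior_df_equals_classical_t(self, two_group_design, ba_contrast):
        m, _ = sim_log_matrix(300, two_group_design, de_fraction=0.2, seed=30)
        fit = contrasts_fit(lm_fit(m, two_group_design), ba_contrast)
        mod = moderated_stats(fit, prior=FDistPrior(0.0, 1.0))
        t_classical = fit.coefficients[:, 0] / (fit.stdev_unscaled[:, 0] * fit.sigma)
        p_classical = 2 * stats.t.sf(np.abs(t_classical), fit.df_residual)
        np.testing.assert_allclose(mod.t[:, 0], t_classical, atol=1e-12)
        np.testing.assert_allclose(mod.p_value[:, 0], p_classical, atol=1e-12)

    def test_hand_computed_moderated_t(self, two_group_design, ba_contrast):
        # beta=1, u=0.5, sigma=1, df=4, d0=4, s0^2=1 -> s2_post=1, t=2, df_total=8
        m, _ = sim_log_matrix(10, two_group_design, de_fraction=0.0, seed=31)
        fit = contrasts_fit(lm_fit(m, two_group_design), ba_contrast)
        fit.coefficients[0, 0] = 1.0
        fit.stdev_unscaled[0, 0] = 0.5
        fit.sigma[0] = 1.0
        fit.df_residual[0] = 4.0
        mod = moderated_stats(fit, prior=FDistPrior(4.0, 1.0))
        assert mod.s2_post[0] == pytest.approx(1.0)
        assert mod.t[0, 0] == pytest.approx(2.0)
        assert mod.df_total[0] == pytest.approx(8.0)
        assert mod.p_value[0, 0] == pytest.approx(2 * stats.t.sf(2.0, 8.0))

    def test_single_contrast_F_equals_t_squared(self, two_group_design, ba_contrast):
        m, _ = sim_log_matrix(100, two_group_design, de_fraction=0.1, seed=32)
        mod = moderated_stats(contrasts_fit(lm_fit(m, two_group_design), ba_contrast))
        np.testing.assert_allclose(mod.F, mod.t[:, 0] ** 2, atol=1e-12)
        np.testing.assert_allclose(mod.F_p, mod.p_value[:, 0], atol=1e-12)

    def test_shrinkage_direction(self, two_group_design, ba_contrast):
        # |moderated t| >= |classical t| exactly when s2 > s2_prior
        m, _ = sim_log_matrix(2000, two_group_design, de_fraction=0.0, seed=33)
        fit = contrasts_fit(lm_fit(m, two_group_design), ba_contrast)
        mod = moderated_stats(fit)
        t_classical = fit.coefficients[:, 0] / (fit.stdev_unscaled[:, 0] * fit.sigma)
        bigger = np.abs(mod.t[:, 0]) >= np.abs(t_classical) - 1e-12
        assert np.array_equal(bigger, fit.sigma**2 >= mod.s2_prior - 1e-12)

    def test_robust_gives_outlier_smaller_prior_df(self, two_group_design, ba_contrast):
        m, _ = sim_log_matrix(2000, two_group_design, de_fraction=0.0, seed=34)
        m.values[0] += np.array([0, 0, 0, 30, -30, 30.0])   # huge variance outlier
        fit = contrasts_fit(lm_fit(m, two_group_design), ba_contrast)
        mod_r = moderated_stats(fit, robust=True)
        d0 = np.asarray(mod_r.df_prior)
        assert d0[0] < np.median(d0) / 10
        mod = moderated_stats(fit)
        assert abs(mod_r.t[0, 0]) <= abs(mod.t[0, 0])  # outlier squeezed less

    def test_all_zero_df_rejected(self):
        d = DesignSpec.from_groups(["A", "B"])
        m, _ = sim_log_matrix(20, d, de_fraction=0.0, seed=35)
        fit = lm_fit(m, d)
        with pytest.raises(ValueError, match="residual df"):
            moderated_stats(fit)


class TestTreat:
    def _fit(self, two_group_design, ba_contrast):
        m, _ = sim_log_matrix(200, two_group_design, de_fraction=0.3,
                              logfc_sd=2.0, seed=36)
        return moderated_stats(contrasts_fit(lm_fit(m, two_group_design), ba_contrast))

    def test_zero_threshold_equals_moderated_p(self, two_group_design, ba_contrast):
        mod = self._fit(two_group_design, ba_contrast)
        tr = treat(mod, 0.0)
        np.testing.assert_allclose(tr.p_value, mod.p_value, atol=1e-12)

    def test_hand_computed_tail_sum(self, two_group_design, ba_contrast):
        mod = self._fit(two_group_design, ba_contrast)
        mod.coefficients[0, 0] = 2.0
        mod.stdev_unscaled[0, 0] = 0.5
        mod.s2_post[0] = 1.0
        mod.df_total[0] = 8.0
        tr = treat(mod, 1.0)
        expected = stats.t.sf(2.0, 8.0) + stats.t.sf(6.0, 8.0)
        assert tr.p_value[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_threshold(self, two_group_design, ba_contrast):
        mod = self._fit(two_group_design, ba_contrast)
        last = mod.p_value.copy()
        for lfc in (0.5, 1.0, 2.0, 8.0):
            p = treat(mod, lfc).p_value
            assert (p >= last - 1e-12).all()
            last = p
        assert (treat(mod, 50.0).p_value > 0.99).all()

    def test_negative_threshold_rejected(self, two_group_design, ba_contrast):
        mod = self._fit(two_group_design, ba_contrast)
        with pytest.raises(ValueError, match="non-negative"):
            treat(mod, -1.0)


class TestPAdjust:
    def test_bh_step_up_example(self):
        # brute-force step-up: p(i) * n/i, cumulative min from the largest
        np.testing.assert_allclose(p_adjust(np.array([0.01, 0.02, 0.03]), "BH"),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        for method in ("BH", "BY", "holm", "bonferroni"):
            assert p_adjust(np.array([0.2]), method)[0] == pytest.approx(0.2)

    def test_bonferroni(self):
        np.testing.assert_allclose(p_adjust(np.array([0.01, 0.4]), "bonferroni"),
                                   [0.02, 0.8])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            p_adjust(np.array([1.5]), "BH")

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_bh_matches_brute_force(self, ps):
        p = np.array(ps)
        n = p.size
        order = np.argsort(p, kind="mergesort")
        stepped = p[order] * n / np.arange(1, n + 1)
        brute = np.minimum.accumulate(stepped[::-1])[::-1].clip(max=1.0)
        expected = np.empty(n)
        expected[order] = brute
        np.testing.assert_allclose(p_adjust(p, "BH"), expected, atol=1e-12)


class TestTopTable:
    @pytest.fixture
    def mod(self, two_group_design, ba_contrast):
        m, _ = sim_log_matrix(120, two_group_design, de_fraction=0.2, seed=40)
        return moderated_stats(contrasts_fit(lm_fit(m, two_group_design),
                                             ba_contrast, names=["BvsA"]))

    def test_sorted_by_p(self, mod):
        tab = top_table(mod, coef="BvsA", number=50)
        assert (np.diff(tab["P.Value"].to_numpy()) >= 0).all()

    def test_number_larger_than_G_returns_all(self, mod):
        assert len(top_table(mod, coef="BvsA", number=10_000)) == 120

    def test_counts_agree_with_decide_tests(self, mod):
        tab = top_table(mod, coef="BvsA", number=None)
        for cutoff in (0.01, 0.05, 0.2):
            n_tab = int((tab["adj.P.Val"] <= cutoff).sum())
            dt = decide_tests(mod, p_threshold=cutoff)
            assert n_tab == int((dt.codes != 0).sum())

    def test_unknown_coef_rejected(self, mod):
        with pytest.raises(KeyError):
            top_table(mod, coef="nope")


class TestDecideTests:
    @pytest.fixture
    def mod3(self, two_group_design):
        m, _ = sim_log_matrix(50, two_group_design, de_fraction=0.3, seed=41)
        C = np.array([[1.0, -1.0, 0.5], [-1.0, 1.0, 0.5]])
        return moderated_stats(contrasts_fit(lm_fit(m, two_group_design), C,
                                             names=["c1", "c2", "c3"]))

    def test_threshold_one_gives_sign_of_t(self, mod3):
        dt = decide_tests(mod3, p_threshold=1.0)
        np.testing.assert_array_equal(dt.codes, np.sign(mod3.t).astype(int))

    def test_tiny_threshold_all_zero_on_null(self, two_group_design, ba_contrast):
        m, _ = sim_log_matrix(100, two_group_design, de_fraction=0.0, seed=42)
        mod = moderated_stats(contrasts_fit(lm_fit(m, two_group_design), ba_contrast))
        dt = decide_tests(mod, p_threshold=1e-300)
        assert (dt.codes == 0).all()

    def test_global_matches_brute_force_pooled_adjustment(self, mod3):
        dt = decide_tests(mod3, method="global", p_threshold=0.05)
        pooled = p_adjust(mod3.p_value.ravel(), "BH").reshape(mod3.p_value.shape)
        expected = np.where(pooled <= 0.05, np.sign(mod3.t).astype(int), 0)
        np.testing.assert_array_equal(dt.codes, expected)

    def test_global_vs_separate_differ_only_by_pooling(self, mod3):
        sep = decide_tests(mod3, method="separate", p_threshold=0.05)
        glo = decide_tests(mod3, method="global", p_threshold=0.05)
        sep_adj = np.column_stack([p_adjust(mod3.p_value[:, j], "BH")
                                   for j in range(3)])
        pooled = p_adjust(mod3.p_value.ravel(), "BH").reshape(mod3.p_value.shape)
        disagree = (sep.codes != glo.codes)
        reordered = (sep_adj <= 0.05) != (pooled <= 0.05)
        np.testing.assert_array_equal(disagree, reordered)

    def test_bad_threshold_rejected(self, mod3):
        with pytest.raises(ValueError, match="p_threshold"):
            decide_tests(mod3, p_threshold=0.0)


class TestPropTrueNull:
    @pytest.mark.parametrize("method", ["mean", "hist", "convest", "lfdr"])
    def test_uniform_p_gives_pi0_near_one(self, method):
        rng = np.random.default_rng(50)
        p = rng.uniform(0, 1, 10000)
        assert 0.93 <= prop_true_null(p, method) <= 1.0

    @pytest.mark.parametrize("method", ["mean", "hist", "convest", "lfdr"])
    def test_saturated_alternative_gives_small_pi0(self, method):
        rng = np.random.default_rng(51)
        p = rng.uniform(0, 1e-6, 1000)
        assert prop_true_null(p, method) < 0.05

    def test_mean_formula(self):
        with pytest.warns(UserWarning):
            assert prop_true_null(np.array([0.1, 0.2, 0.3]), "mean") == pytest.approx(0.4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            prop_true_null(np.array([]))
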