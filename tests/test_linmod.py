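import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genelm.datamodel import BlockStructure, DesignSpec, ExpressionMatrix
from genelm.linmod import (array_weights, contrasts_fit, duplicate_correlation,
                           lm_fit, remove_batch_effect)
from genelm.simulate import sim_blocks, sim_log_matrix


def _matrix(vals, **kw):
    vals = np.atleast_2d(np.asarray(vals, dtype=float))
    return ExpressionMatrix(vals, [f"g{i}" for i in range(vals.shape[0])],
                            [f"s{j}" for j in range(vals.shape[1])], **kw)


class TestLmFit:
    def test_two_group_hand_computation(self):
        # y = [1,2,3,4], groups [A,A,B,B]: means 1.5/3.5, sigma^2 = 0.5, df = 2
        d = DesignSpec.from_groups(["A", "A", "B", "B"])
        fit = lm_fit(_matrix([1.0, 2.0, 3.0, 4.0]), d)
        np.testing.assert_allclose(fit.coefficients[0], [1.5, 3.5])
        np.testing.assert_allclose(fit.sigma[0], np.sqrt(0.5))
        assert fit.df_residual[0] == 2
        np.testing.assert_allclose(fit.stdev_unscaled[0], [np.sqrt(0.5), np.sqrt(0.5)])

    def test_weight_scale_invariance(self, two_group_design):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 6))
        w = rng.uniform(0.5, 2.0, size=(20, 6))
        m1 = _matrix(vals, obs_weights=w)
        m2 = _matrix(vals, obs_weights=10 * w)
        f1 = lm_fit(m1, two_group_design)
        f2 = lm_fit(m2, two_group_design)
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, rtol=1e-10)
        t1 = f1.coefficients / (f1.stdev_unscaled * f1.sigma[:, None])
        t2 = f2.coefficients / (f2.stdev_unscaled * f2.sigma[:, None])
        np.testing.assert_allclose(t1, t2, rtol=1e-10)

    def test_saturated_design_zero_df(self):
        d = DesignSpec.from_groups(["A", "B"])
        fit = lm_fit(_matrix([2.0, 5.0]), d)
        assert fit.df_residual[0] == 0
        assert np.isnan(fit.sigma[0])
        np.testing.assert_allclose(fit.coefficients[0], [2.0, 5.0])

    def test_missing_value_reduces_df(self):
        d = DesignSpec.from_groups(["A", "A", "A", "B", "B", "B"])
        y = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        fit = lm_fit(_matrix(y), d)
        assert fit.df_residual[0] == 3   # 5 observations - 2 coefficients
        np.testing.assert_allclose(fit.coefficients[0], [1.5, 5.0])

    def test_gls_rho_zero_equals_ols(self, two_group_design):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(size=(30, 6)))
        block = BlockStructure(block=["b1", "b1", "b2", "b2", "b3", "b3"],
                               correlation=1e-15)
        f_ols = lm_fit(m, two_group_design)
        f_gls = lm_fit(m, two_group_design, block=block)
        np.testing.assert_allclose(f_gls.coefficients, f_ols.coefficients, atol=1e-10)
        np.testing.assert_allclose(f_gls.sigma, f_ols.sigma, atol=1e-10)

    def test_reparameterization_invariance(self):
        # fitted values and sigma invariant under invertible design change
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(8), np.repeat([0, 1], 4), rng.normal(size=8)])
        T = np.array([[1.0, 2.0, 0.0], [0.0, 1.0, 1.0], [0.0, 0.0, 3.0]])
        d1 = DesignSpec(X, ["a", "b", "c"])
        d2 = DesignSpec(X @ T, ["a2", "b2", "c2"])
        m = _matrix(rng.normal(size=(15, 8)))
        f1, f2 = lm_fit(m, d1), lm_fit(m, d2)
        np.testing.assert_allclose(f1.coefficients @ X.T, f2.coefficients @ (X @ T).T,
                                   rtol=1e-9)
        np.testing.assert_allclose(f1.sigma, f2.sigma, rtol=1e-9)

    def test_robust_downweights_outlier(self):
        d = DesignSpec(np.ones((8, 1)), ["mean"])
        y = np.array([1.0, 1.1, 0.9, 1.0, 1.05, 0.95, 1.0, 15.0])
        f_ls = lm_fit(_matrix(y), d)
        f_rob = lm_fit(_matrix(y), d, robust=True)
        assert abs(f_rob.coefficients[0, 0] - 1.0) < abs(f_ls.coefficients[0, 0] - 1.0)
        assert f_rob.df_residual[0] == f_ls.df_residual[0]

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        d = DesignSpec(X, ["a", "b"])
        with pytest.raises(ValueError, match="rank"):
            lm_fit(_matrix([1.0, 2.0, 3.0, 4.0]), d)


class TestContrastsFit:
    def test_identity_contrast_noop(self, two_group_design):
        rng = np.random.default_rng(3)
        f = lm_fit(_matrix(rng.normal(size=(10, 6))), two_group_design)
        f2 = contrasts_fit(f, np.eye(2), names=f.col_names)
        np.testing.assert_allclose(f2.coefficients, f.coefficients)
        np.testing.assert_allclose(f2.stdev_unscaled, f.stdev_unscaled)
        np.testing.assert_allclose(f2.sigma, f.sigma)

    def test_two_group_difference_hand_computation(self):
        d = DesignSpec.from_groups(["A", "A", "B", "B"])
        f = lm_fit(_matrix([1.0, 2.0, 3.0, 4.0]), d)
        cf = contrasts_fit(f, np.array([-1.0, 1.0]), names=["B-A"])
        np.testing.assert_allclose(cf.coefficients[0, 0], 2.0)
        np.testing.assert_allclose(cf.stdev_unscaled[0, 0], 1.0)

    def test_orthogonal_design_variance_additivity(self):
        # diagonal unscaled covariance: contrast variance = sum c_k^2 var_k
        d = DesignSpec.from_groups(["A", "A", "A", "B"])
        rng = np.random.default_rng(4)
        f = lm_fit(_matrix(rng.normal(size=(5, 4))), d)
        c = np.array([2.0, -3.0])
        cf = contrasts_fit(f, c)
        expected = np.sqrt(np.sum(c**2 * f.stdev_unscaled[0] ** 2))
        np.testing.assert_allclose(cf.stdev_unscaled[:, 0], expected)

    def test_composition(self, two_group_design):
        rng = np.random.default_rng(5)
        f = lm_fit(_matrix(rng.normal(size=(12, 6))), two_group_design)
        C1 = np.array([[1.0, 1.0], [0.0, 1.0]])
        C2 = np.array([[1.0], [-2.0]])
        a = contrasts_fit(contrasts_fit(f, C1), C2)
        b = contrasts_fit(f, C1 @ C2)
        np.testing.assert_allclose(a.coefficients, b.coefficients, rtol=1e-10)
        np.testing.assert_allclose(a.stdev_unscaled, b.stdev_unscaled, rtol=1e-10)

    def test_dimension_mismatch(self, two_group_design):
        rng = np.random.default_rng(6)
        f = lm_fit(_matrix(rng.normal(size=(5, 6))), two_group_design)
        with pytest.raises(ValueError, match="rows"):
            contrasts_fit(f, np.ones((3, 1)))


class TestDuplicateCorrelation:
    def test_recovers_true_correlation(self):
        m, blocks = sim_blocks(4000, 6, 2, rho=0.5, seed=5)
        d = DesignSpec(np.ones((12, 1)), ["intercept"])
        rho = duplicate_correlation(m, d, blocks)
        assert abs(rho - 0.5) < 0.05

    def test_null_correlation_near_zero(self):
        m, blocks = sim_blocks(4000, 6, 2, rho=0.0, seed=6)
        d = DesignSpec(np.ones((12, 1)), ["intercept"])
        assert abs(duplicate_correlation(m, d, blocks)) < 0.05

    def test_exact_duplicates_clamp_high(self):
        rng = np.random.default_rng(7)
        half = rng.normal(8, 1, size=(200, 4))
        vals = np.repeat(half, 2, axis=1)     # columns 0=1, 2=3, ...
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(200)],
                             [f"s{j}" for j in range(8)])
        blocks = ["b1", "b1", "b2", "b2", "b3", "b3", "b4", "b4"]
        d = DesignSpec(np.ones((8, 1)), ["intercept"])
        assert duplicate_correlation(m, d, blocks) >= 0.98

    def test_all_singleton_blocks_rejected(self, small_matrix):
        d = DesignSpec(np.ones((6, 1)), ["intercept"])
        with pytest.raises(ValueError, match="singleton"):
            duplicate_correlation(small_matrix, d, [f"b{j}" for j in range(6)])


class TestArrayWeights:
    def test_homoscedastic_weights_near_one(self, two_group_design):
        m, _ = sim_log_matrix(3000, two_group_design, de_fraction=0.0, seed=8)
        w = array_weights(m, two_group_design)
        assert np.all((w > 0.8) & (w < 1.25))

    def test_inflated_variance_sample_downweighted(self, two_group_design):
        m, _ = sim_log_matrix(3000, two_group_design, de_fraction=0.0,
                              d0=np.inf, s0_sq=0.04, seed=9)
        rng = np.random.default_rng(10)
        # give sample 0 four times the error variance
        m.values[:, 0] += rng.standard_normal(3000) * np.sqrt(3 * 0.04)
        w = array_weights(m, two_group_design)
        assert w[0] / w[1:].mean() < 0.4

    def test_geometric_mean_one(self, two_group_design):
        m, _ = sim_log_matrix(500, two_group_design, de_fraction=0.0, seed=11)
        w = array_weights(m, two_group_design)
        assert abs(np.mean(np.log(w))) < 1e-8

    def test_needs_enough_samples(self):
        d = DesignSpec.from_groups(["A", "A", "B"])
        m, _ = sim_log_matrix(50, d, de_fraction=0.0, seed=1)
        with pytest.raises(ValueError, match="N > p"):
            array_weights(m, d)


class TestRemoveBatchEffect:
    def test_additive_shift_removed_exactly(self):
        rng = np.random.default_rng(12)
        base = rng.normal(8, 1, size=(100, 3))
        vals = np.hstack([base, base + 3.0])
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(100)],
                             [f"s{j}" for j in range(6)])
        out = remove_batch_effect(m, ["A"] * 3 + ["B"] * 3)
        np.testing.assert_allclose(out.values[:, :3].mean(axis=1),
                                   out.values[:, 3:].mean(axis=1), atol=1e-10)

    def test_orthogonal_treatment_preserved(self):
        # treatment alternates within batches: exactly orthogonal to batch
        rng = np.random.default_rng(13)
        G = 50
        treat = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        batch = ["A"] * 4 + ["B"] * 4
        effect = rng.normal(0, 2, size=G)
        vals = rng.normal(size=(G, 8)) + effect[:, None] * treat[None, :]
        vals[:, 4:] += 5.0
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(G)],
                             [f"s{j}" for j in range(8)])
        d = DesignSpec(np.column_stack([np.ones(8), treat]), ["intercept", "treat"])
        out = remove_batch_effect(m, batch, design=d)
        diff_before = vals[:, treat == 1].mean(axis=1) - vals[:, treat == 0].mean(axis=1)
        diff_after = out.values[:, treat == 1].mean(axis=1) - out.values[:, treat == 0].mean(axis=1)
        np.testing.assert_allclose(diff_after, diff_before, atol=1e-10)

    def test_single_batch_unchanged(self, small_matrix):
        out = remove_batch_effect(small_matrix, ["A"] * 6)
        np.testing.assert_array_equal(out.values, small_matrix.values)

    def test_aliased_batch_rejected(self):
        m, _ = sim_log_matrix(20, DesignSpec.from_groups(["A", "A", "B", "B"]),
                              de_fraction=0.0, seed=1)
        d = DesignSpec.from_groups(["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="aliased"):
            remove_batch_effect(m, ["x", "x", "y", "y"], design=d)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_gls_matches_whitened_ols(seed):
    """GLS under block correlation equals OLS on explicitly whitened data."""
    rng = np.random.default_rng(seed)
    rho = rng.uniform(-0.4, 0.9)
    blocks = ["b1", "b1", "b2", "b2", "b3", "b3"]
    V = np.eye(6)
    for i in range(6):
        for j in range(6):
            if i != j and blocks[i] == blocks[j]:
                V[i, j] = rho
    L = np.linalg.cholesky(V)
    X = DesignSpec.from_groups(["A"] * 3 + ["B"] * 3).design
    Y = rng.normal(size=(5, 6))
    m = ExpressionMatrix(Y, [f"g{i}" for i in range(5)], [f"s{j}" for j in range(6)])
    f = lm_fit(m, DesignSpec(X, ["A", "B"]),
               block=BlockStructure(block=blocks, correlation=rho))
    Xw = np.linalg.solve(L, X)
    Yw = np.linalg.solve(L, Y.T).T
    beta, *_ = np.linalg.lstsq(Xw, Yw.T, rcond=None)
    np.testing.assert_allclose(f.coefficients, beta.T, atol=1e-8)
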