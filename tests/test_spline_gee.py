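import numpy as np
import pytest
from scipy import stats

from gravida.spline_gee import (
    DesignMatrix,
    SplineSpec,
    bspline_basis,
    build_design,
    fit_gee,
    joint_wald,
    predict_curve,
    spline_knots,
    tensor_product,
)


# -- independent textbook Cox-de Boor recursion (oracle) --------------------


def cox_de_boor(x, knots, degree):
    """Brute-force B-spline basis via the Cox-de Boor recursion."""
    knots = np.asarray(knots, float)
    n_basis = len(knots) - degree - 1
    out = np.zeros((len(x), n_basis))
    for j, xx in enumerate(x):
        # degree-0 indicator functions (half-open, last interval closed)
        b = np.zeros((len(knots) - 1,))
        for i in range(len(knots) - 1):
            if knots[i] <= xx < knots[i + 1] or (
                xx == knots[-1] and knots[i] < knots[i + 1] == knots[-1]
            ):
                b[i] = 1.0
        for d in range(1, degree + 1):
            nb = np.zeros(len(knots) - d - 1)
            for i in range(len(nb)):
                left = 0.0
                if knots[i + d] > knots[i]:
                    left = (xx - knots[i]) / (knots[i + d] - knots[i]) * b[i]
                right = 0.0
                if knots[i + d + 1] > knots[i + 1]:
                    right = (
                        (knots[i + d + 1] - xx)
                        / (knots[i + d + 1] - knots[i + 1])
                        * b[i + 1]
                    )
                nb[i] = left + right
            b = nb
        out[j] = b[:n_basis]
    return out


class TestBSplineBasis:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-3, 10, 200)
        full, _ = bspline_basis(x, SplineSpec(df=8), drop_first=False)
        assert np.allclose(full.sum(axis=1), 1.0, atol=1e-12)

    def test_nonnegative_everywhere(self):
        x = np.linspace(0, 1, 101)
        full, _ = bspline_basis(x, SplineSpec(df=5), drop_first=False)
        assert (full >= -1e-14).all()

    @pytest.mark.parametrize("df", [3, 5, 8])
    def test_matches_textbook_de_boor(self, df):
        rng = np.random.default_rng(df)
        x = np.sort(rng.uniform(0, 10, 50))
        x[0], x[-1] = 0.0, 10.0
        spec = SplineSpec(df=df)
        ours, knots = bspline_basis(x, spec, drop_first=False)
        oracle = cox_de_boor(x, knots, spec.degree)
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_quantile_interior_knots(self):
        x = np.arange(101, dtype=float)
        knots = spline_knots(x, SplineSpec(df=8))  # 5 interior knots
        interior = knots[4:-4]
        assert len(interior) == 5
        assert np.allclose(interior, [100 / 6, 200 / 6, 50, 400 / 6, 500 / 6])

    def test_errors(self):
        with pytest.raises(ValueError):
            bspline_basis(np.array([0.0, 1.0, 2.0]), SplineSpec(df=8))
        basis, knots = bspline_basis(np.linspace(0, 1, 20), SplineSpec(df=4))
        with pytest.raises(ValueError):
            bspline_basis(np.array([1.5]), SplineSpec(df=4), knots=knots)

    def test_df_counts_retained_columns(self):
        basis, _ = bspline_basis(np.linspace(0, 1, 30), SplineSpec(df=8))
        assert basis.shape[1] == 8
        basis3, _ = bspline_basis(np.linspace(0, 1, 30), SplineSpec(df=3))
        assert basis3.shape[1] == 3


class TestTensorProduct:
    def test_all_ones_factor_is_identity(self):
        a = np.arange(12.0).reshape(4, 3)
        ones = np.ones((4, 1))
        assert np.array_equal(tensor_product(a, ones), a)

    def test_column_count_and_loop_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(5, 2)), rng.normal(size=(5, 3))
        tp = tensor_product(a, b)
        assert tp.shape == (5, 6)
        explicit = np.empty((5, 6))
        k = 0
        for i in range(2):
            for j in range(3):
                explicit[:, k] = a[:, i] * b[:, j]
                k += 1
        assert np.array_equal(tp, explicit)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            tensor_product(np.ones((3, 2)), np.ones((4, 2)))


def _design(X, cluster_ids, blocks=None):
    if blocks is None:
        blocks = {"all": np.arange(X.shape[1])}
    return DesignMatrix(X, blocks, np.asarray(cluster_ids))


class TestFitGEE:
    def test_singleton_clusters_equal_ols_exactly(self):
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        y = np.array([1.0, 2.0, 3.0])
        fit = fit_gee(y, _design(X, [0, 1, 2]))
        assert fit.beta == pytest.approx([1.0, 1.0], abs=1e-10)

    def test_alpha_zero_equal_size_clusters_reproduce_ols(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = X @ [1.0, 2.0] + rng.normal(size=40)
        fit = fit_gee(y, _design(X, np.repeat(np.arange(10), 4)), alpha_fixed=0.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-8)

    def test_balanced_two_obs_clusters_match_gls_closed_form(self):
        rng = np.random.default_rng(3)
        G, alpha = 30, 0.4
        X = np.column_stack([np.ones(2 * G), rng.normal(size=2 * G)])
        y = X @ [0.5, -1.0] + rng.normal(size=2 * G)
        cl = np.repeat(np.arange(G), 2)
        fit = fit_gee(y, _design(X, cl), alpha_fixed=alpha)
        # direct GLS with the same 2x2 block correlation
        R_inv = np.linalg.inv(np.array([[1.0, alpha], [alpha, 1.0]]))
        A = np.zeros((2, 2))
        b = np.zeros(2)
        for i in range(G):
            Xi, yi = X[2 * i : 2 * i + 2], y[2 * i : 2 * i + 2]
            A += Xi.T @ R_inv @ Xi
            b += Xi.T @ R_inv @ yi
        assert np.allclose(fit.beta, np.linalg.solve(A, b), atol=1e-8)

    def test_alpha_recovers_random_intercept_icc(self):
        rng = np.random.default_rng(4)
        G, n = 200, 5
        cl = np.repeat(np.arange(G), n)
        y = np.repeat(rng.normal(0, 1, G), n) + rng.normal(0, 1, G * n)
        fit = fit_gee(y, _design(np.ones((G * n, 1)), cl))
        assert fit.alpha == pytest.approx(0.5, abs=0.1)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        t = np.tile(np.arange(6, dtype=float), 40)
        cl = np.repeat(np.arange(40), 6)
        y = np.sin(t) + np.repeat(rng.normal(0, 1, 40), 6) + rng.normal(0, 1, 240)
        D = build_design(t, cl, SplineSpec(df=3))
        f1, f2 = fit_gee(y, D), fit_gee(10.0 * y, D)
        assert np.allclose(f2.beta, 10.0 * f1.beta, atol=1e-8)
        w1 = joint_wald(f1, "time_spline")
        w2 = joint_wald(f2, "time_spline")
        assert w1.statistic == pytest.approx(w2.statistic, abs=1e-8)

    def test_robust_vs_naive_agree_under_true_exchangeability(self):
        rng = np.random.default_rng(6)
        G, n = 500, 4
        cl = np.repeat(np.arange(G), n)
        x = rng.normal(size=G * n)
        y = 1.0 + 0.3 * x + np.repeat(rng.normal(0, 0.8, G), n) + rng.normal(0, 1, G * n)
        fit = fit_gee(y, _design(np.column_stack([np.ones(G * n), x]), cl))
        ratio = fit.se_robust / np.sqrt(np.diag(fit.cov_naive))
        assert ((ratio > 0.8) & (ratio < 1.2)).all()

    def test_matches_statsmodels_gee(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        from statsmodels.genmod.cov_struct import Exchangeable
        from statsmodels.genmod.generalized_estimating_equations import GEE

        rng = np.random.default_rng(7)
        rows, ys, cl = [], [], []
        for i in range(60):
            n = int(rng.integers(3, 8))
            x = rng.normal(size=(n, 2))
            ys.append(
                1.0 + 0.5 * x[:, 0] - 0.8 * x[:, 1]
                + rng.normal(0, 1) + rng.normal(0, 1, n)
            )
            rows.append(x)
            cl.extend([i] * n)
        X = np.column_stack([np.ones(len(cl)), np.vstack(rows)])
        y = np.concatenate(ys)
        ours = fit_gee(y, _design(X, np.array(cl)))
        theirs = GEE(
            y, X, groups=np.array(cl), cov_struct=Exchangeable(),
            family=statsmodels.families.Gaussian(),
        ).fit(maxiter=200, ctol=1e-10)
        assert np.allclose(ours.beta, theirs.params, rtol=1e-4)
        assert np.allclose(ours.se_robust, theirs.bse, rtol=1e-4)

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.ones(8), np.ones(8)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_gee(np.arange(8.0), _design(X, np.repeat([0, 1], 4)))

    def test_serialisation_round_trip(self):
        from gravida.spline_gee import GEEFit

        X = np.column_stack([np.ones(6), np.arange(6.0)])
        fit = fit_gee(np.arange(6.0), _design(X, np.repeat([0, 1, 2], 2)))
        restored = GEEFit.from_json(fit.to_json())
        assert np.allclose(restored.beta, fit.beta)
        assert np.allclose(restored.cov_robust, fit.cov_robust)


class TestJointWald:
    def _fit(self):
        rng = np.random.default_rng(8)
        t = np.tile(np.arange(8, dtype=float), 60)
        cl = np.repeat(np.arange(60), 8)
        y = np.repeat(rng.normal(0, 1, 60), 8) + rng.normal(0, 1, 480)
        return fit_gee(y, build_design(t, cl, SplineSpec(df=3)))

    def test_zero_block_statistic_zero(self):
        fit = self._fit()
        fit.beta[fit.blocks["time_spline"]] = 0.0
        res = joint_wald(fit, "time_spline")
        assert res.statistic == 0.0 and res.p == 1.0

    def test_single_df_equals_z_test(self):
        fit = self._fit()
        idx = int(fit.blocks["time_spline"][0])
        res = joint_wald(fit, [idx])
        z = fit.beta[idx] / fit.se_robust[idx]
        assert res.statistic == pytest.approx(z**2, rel=1e-10)
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-8)

    def test_chi2_tail_oracle(self):
        assert stats.chi2.sf(3.841459, 1) == pytest.approx(0.0500, abs=1e-4)
        fit = self._fit()
        res = joint_wald(fit, "time_spline")
        assert res.p == pytest.approx(stats.chi2.sf(res.statistic, res.df), rel=1e-12)

    def test_empty_and_out_of_range_blocks(self):
        fit = self._fit()
        with pytest.raises(ValueError):
            joint_wald(fit, [])
        with pytest.raises(IndexError):
            joint_wald(fit, [99])

    def test_null_calibration_type_one_error_and_uniformity(self):
        # 500 seeded replicates with no time effect: joint Wald p-values on
        # the spline block are ~U(0,1); rejection at .05 within [0.03, 0.08]
        spec = SplineSpec(df=3)
        pvals = np.empty(500)
        G, n = 100, 8
        t = np.tile(np.arange(n, dtype=float), G)
        cl = np.repeat(np.arange(G), n)
        for rep in range(500):
            rng = np.random.default_rng(1000 + rep)
            y = np.repeat(rng.normal(0, 0.7, G), n) + rng.normal(0, 1, G * n)
            fit = fit_gee(y, build_design(t, cl, spec))
            pvals[rep] = joint_wald(fit, "time_spline").p
        assert 0.03 <= np.mean(pvals < 0.05) <= 0.08
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPredictCurve:
    def test_in_sample_fitted_values(self):
        rng = np.random.default_rng(9)
        t = np.tile(np.arange(6, dtype=float), 30)
        cl = np.repeat(np.arange(30), 6)
        y = t * 0.2 + rng.normal(0, 1, 180)
        D = build_design(t, cl, SplineSpec(df=3))
        fit = fit_gee(y, D)
        yhat, se = predict_curve(fit, D.values)
        assert np.allclose(yhat, D.values @ fit.beta)
        assert (se > 0).all()

    def test_intercept_only_flat(self):
        y = np.array([1.0, 3.0, 5.0, 7.0])
        fit = fit_gee(y, _design(np.ones((4, 1)), [0, 0, 1, 1]))
        yhat, _ = predict_curve(fit, np.ones((3, 1)))
        assert np.allclose(yhat, yhat[0])

    def test_matrix_product_oracle(self):
        rng = np.random.default_rng(10)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        fit = fit_gee(rng.normal(size=20), _design(X, np.repeat(np.arange(10), 2)))
        Xn = np.column_stack([np.ones(5), np.linspace(-2, 2, 5)])
        yhat, se = predict_curve(fit, Xn)
        assert np.allclose(yhat, Xn @ fit.beta, atol=1e-10)
        expected_se = np.sqrt(np.diag(Xn @ fit.cov_robust @ Xn.T))
        assert np.allclose(se, expected_se, atol=1e-10)

    def test_column_mismatch(self):
        fit = fit_gee(
            np.arange(4.0), _design(np.ones((4, 1)), [0, 0, 1, 1])
        )
        with pytest.raises(ValueError):
            predict_curve(fit, np.ones((2, 3)))


class TestDesignMatrix:
    def test_blocks_must_partition_columns(self):
        with pytest.raises(ValueError):
            DesignMatrix(np.ones((3, 2)), {"a": np.array([0])}, np.zeros(3))
        with pytest.raises(ValueError):
            DesignMatrix(
                np.ones((3, 2)),
                {"a": np.array([0, 1]), "b": np.array([1])},
                np.zeros(3),
            )

    def test_build_design_block_layout(self):
        rng = np.random.default_rng(11)
        t = np.tile(np.linspace(0, 10, 12), 10)
        cl = np.repeat(np.arange(10), 12)
        age = np.repeat(rng.uniform(20, 45, 10), 12)
        D = build_design(
            t, cl, SplineSpec(df=4), age=age, covariate_spec=SplineSpec(df=3)
        )
        assert set(D.blocks) == {"intercept", "time_spline", "age_spline", "time_x_age"}
        assert len(D.blocks["time_spline"]) == 4
        assert len(D.blocks["time_x_age"]) == 12
        assert D.n_columns == 1 + 4 + 3 + 12
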