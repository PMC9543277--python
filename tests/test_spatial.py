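import math
import warnings

import numpy as np
import pytest

import paranet as pn
from paranet.spatial import (
    ConvergenceWarning,
    SpatialStatsError,
    _concentrated_loglik,
    distance_band_weights,
    great_circle_km,
    nagelkerke_r2,
    ols_fit,
    sar_error_fit,
    simulate_sar_response,
)


def moran_i(x, W):
    """Hand-rolled Moran's I on a row-standardised weights matrix."""
    z = x - x.mean()
    w = W.matrix.toarray()
    return (len(x) / w.sum()) * (z @ w @ z) / (z @ z)


class TestDistanceBandWeights:
    def test_collinear_hand_example(self):
        w = distance_band_weights(np.array([[0.0, 0], [150.0, 0], [300.0, 0]]), 200.0)
        dense = w.matrix.toarray()
        assert np.allclose(dense, [[0, 1, 0], [0.5, 0, 0.5], [0, 1, 0]])
        assert set(map(tuple, np.argwhere(w.binary.toarray()))) == {
            (0, 1), (1, 0), (1, 2), (2, 1),
        }

    def test_isolated_point_keeps_zero_row_and_is_flagged(self):
        w = distance_band_weights(
            np.array([[0.0, 0], [100.0, 0], [10_000.0, 0]]), 200.0
        )
        assert w.islands == [2]
        assert w.matrix.getrow(2).nnz == 0

    def test_interior_hexagons_have_six_neighbors_at_200km(self, hex_world):
        grid, weights = hex_world
        s = grid.metadata["side_km"]
        assert s * math.sqrt(3) == pytest.approx(164.2, abs=0.5)  # < 200 km
        deg = np.asarray(weights.binary.sum(axis=1)).ravel()
        assert deg.max() == 6
        # strict interior cells (one lattice spacing from the hull) all have 6
        cents = grid.centroids()
        pad = 2 * s
        interior = (
            (cents[:, 0] > pad) & (cents[:, 0] < 3300 - pad)
            & (cents[:, 1] > pad) & (cents[:, 1] < 2850 - pad)
        )
        assert (deg[interior] == 6).all()

    def test_rows_sum_to_one_and_diagonal_zero(self, hex_world):
        _, w = hex_world
        rs = np.asarray(w.matrix.sum(axis=1)).ravel()
        assert np.allclose(rs[rs > 0], 1.0, atol=1e-12)
        assert w.matrix.diagonal().sum() == 0.0
        assert (abs(w.binary - w.binary.T)).nnz == 0  # symmetric pre-standardisation

    def test_great_circle_metric(self):
        # 1 degree of longitude on the equator is ~111.2 km
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        d = great_circle_km(pts[:1].repeat(3, 0), pts)
        assert d[1] == pytest.approx(111.19, abs=0.05)
        w = distance_band_weights(pts, 150.0, metric="great_circle")
        assert w.binary.toarray()[0, 1] == 1
        assert w.binary.toarray()[0, 2] == 0

    def test_duplicate_centroids_warn(self):
        with pytest.warns(UserWarning, match="duplicate"):
            distance_band_weights(np.array([[0.0, 0], [0.0, 0]]), 10.0)

    def test_all_isolated_is_an_error(self):
        with pytest.raises(SpatialStatsError):
            distance_band_weights(np.array([[0.0, 0], [1000.0, 0]]), 10.0)


class TestOls:
    def test_exact_linear_data_r2_one(self):
        x = np.arange(20.0)
        X = np.column_stack([np.ones(20), x])
        fit = ols_fit(3.0 + 2.0 * x, X)
        assert fit.r2 == pytest.approx(1.0)
        assert np.allclose(fit.beta, [3.0, 2.0])

    def test_constant_response_r2_zero(self):
        X = np.column_stack([np.ones(30), np.random.default_rng(0).normal(size=30)])
        fit = ols_fit(np.full(30, 5.0), X)
        assert fit.r2 == 0.0

    def test_beta_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(50)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = rng.normal(size=50)
        fit = ols_fit(y, X)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.beta, beta_oracle, atol=1e-10)
        rss = float((y - X @ beta_oracle) @ (y - X @ beta_oracle))
        tss = float(((y - y.mean()) ** 2).sum())
        assert fit.F == pytest.approx(((tss - rss) / 1) / (rss / 48))
        assert fit.df == (1, 48)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(SpatialStatsError, match="rank"):
            ols_fit(np.arange(20.0), X)


class TestLogDeterminant:
    def test_eigenvalue_logdet_matches_dense_slogdet(self, hex_world):
        _, W = hex_world
        assert W.n <= 500
        dense = W.matrix.toarray()
        ev = W.eigenvalues()
        lo, hi = W.lambda_bounds()
        for lam in np.linspace(lo + 0.05, hi - 0.05, 9):
            sign, logdet = np.linalg.slogdet(np.eye(W.n) - lam * dense)
            assert sign > 0
            assert np.log1p(-lam * ev).sum() == pytest.approx(logdet, abs=1e-8)

    def test_lambda_bounds_bracket_zero_with_unit_upper(self, hex_world):
        _, W = hex_world
        lo, hi = W.lambda_bounds()
        assert lo < 0 < hi
        assert hi == pytest.approx(1.0, abs=1e-10)


class TestSarErrorFit:
    def test_lambda_zero_section_reproduces_ols(self, hex_world, design_matrix):
        _, W = hex_world
        y = simulate_sar_response(design_matrix, W, (1.0, 2.0), 0.5, 1.0, seed=301)
        sar0 = sar_error_fit(y, design_matrix, W, fix_lambda=0.0)
        ols = ols_fit(y, design_matrix)
        assert np.allclose(sar0.beta, ols.beta, atol=1e-10)
        assert sar0.logLik == pytest.approx(ols.logLik, abs=1e-10)

    def test_profile_loglik_equals_full_loglik_at_optimum(self, hex_world, design_matrix):
        _, W = hex_world
        y = simulate_sar_response(design_matrix, W, (1.0, 2.0), 0.6, 1.0, seed=302)
        fit = sar_error_fit(y, design_matrix, W)
        # full likelihood evaluated independently at (beta, sigma2, lambda)
        a = W.sparse_identity_minus(fit.lam).toarray()
        e = a @ y - (a @ design_matrix) @ fit.beta
        sign, logdet = np.linalg.slogdet(a)
        full = (
            -0.5 * W.n * math.log(2 * math.pi * fit.sigma2)
            - (e @ e) / (2 * fit.sigma2)
            + logdet
        )
        assert fit.logLik == pytest.approx(full, abs=1e-8)

    def test_sar_loglik_never_below_ols(self, hex_world, design_matrix):
        _, W = hex_world
        for seed in (401, 402, 403):
            y = simulate_sar_response(design_matrix, W, (1.0, 2.0), 0.4, 1.0, seed=seed)
            fit = sar_error_fit(y, design_matrix, W)
            assert fit.logLik >= fit.logLik_ols - 1e-9
            assert fit.lr_vs_ols >= 0.0
            assert fit.lr_df == 1
            lo, hi = fit.lambda_bounds
            assert lo < fit.lam < hi

    def test_lambda_zero_data_fit_near_zero(self, hex_world, design_matrix):
        _, W = hex_world
        hats, diffs = [], []
        for seed in range(20):
            y = simulate_sar_response(design_matrix, W, (1.0, 2.0), 0.0, 1.0, seed=500 + seed)
            fit = sar_error_fit(y, design_matrix, W)
            hats.append(fit.lam)
            diffs.append(fit.logLik - fit.logLik_ols)
        assert abs(np.mean(hats)) < 0.05
        # under the null, 2*(logLik_sar - logLik_ols) ~ chi2(1), whose
        # halved median is 0.227; the median diff should sit well below 0.5
        assert np.median(diffs) < 0.5

    @pytest.mark.parametrize("lam_true", [-0.4, 0.0, 0.4, 0.8])
    def test_parameter_recovery_across_lambda(self, hex_world, design_matrix, lam_true):
        _, W = hex_world
        errs, betas = [], []
        for seed in range(20):
            y = simulate_sar_response(
                design_matrix, W, (1.0, 2.0), lam_true, 1.0, seed=1000 + seed
            )
            fit = sar_error_fit(y, design_matrix, W)
            errs.append(abs(fit.lam - lam_true))
            betas.append(fit.beta)
        assert np.median(errs) < 0.1
        mean_beta = np.mean(betas, axis=0)
        # beta coverage within Monte-Carlo error (sd/sqrt(20) a few percent)
        assert mean_beta == pytest.approx([1.0, 2.0], abs=0.15)

    def test_non_row_standardised_weights_rejected(self, hex_world, design_matrix):
        _, W = hex_world
        import dataclasses

        broken = dataclasses.replace(W, row_standardised=False)
        with pytest.raises(SpatialStatsError):
            sar_error_fit(np.zeros(W.n), design_matrix, W=broken)

    def test_report_fields(self, hex_world, design_matrix):
        _, W = hex_world
        y = simulate_sar_response(design_matrix, W, (1.0, 2.0), 0.4, 1.0, seed=77)
        rep = sar_error_fit(y, design_matrix, W).report()
        assert set(rep) == {"lambda", "beta", "sigma2", "logLik", "nagelkerke_r2",
                            "LR", "df", "n"}
        assert rep["df"] == 1 and rep["n"] == W.n


class TestNagelkerke:
    def test_equal_likelihoods_give_zero(self):
        assert nagelkerke_r2(-120.0, -120.0, 200) == 0.0

    def test_formula_matches_direct_arithmetic(self):
        ll_m, ll_0, n = -100.0, -500.0, 100
        expected = (1 - math.exp(2 / n * (ll_0 - ll_m))) / (1 - math.exp(2 / n * ll_0))
        assert nagelkerke_r2(ll_m, ll_0, n) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_model_likelihood(self):
        vals = [nagelkerke_r2(ll, -300.0, 150) for ll in (-300, -250, -200, -150)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_model_below_null_rejected(self):
        with pytest.raises(SpatialStatsError):
            nagelkerke_r2(-400.0, -300.0, 100)


class TestSimulateSarResponse:
    def test_lambda_zero_gives_iid_noise_at_sigma(self, hex_world, design_matrix):
        _, W = hex_world
        y = simulate_sar_response(design_matrix, W, (1.0, 2.0), 0.0, 1.5, seed=9)
        resid = y - design_matrix @ np.array([1.0, 2.0])
        assert np.std(resid) == pytest.approx(1.5, rel=0.15)

    def test_same_seed_is_deterministic(self, hex_world, design_matrix):
        _, W = hex_world
        a = simulate_sar_response(design_matrix, W, (1.0, 2.0), 0.6, 1.0, seed=4)
        b = simulate_sar_response(design_matrix, W, (1.0, 2.0), 0.6, 1.0, seed=4)
        assert (a == b).all()

    def test_positive_autocorrelation_under_positive_lambda(self, hex_world, design_matrix):
        _, W = hex_world
        morans = []
        for seed in range(20):
            y = simulate_sar_response(design_matrix, W, (1.0, 2.0), 0.7, 1.0, seed=2000 + seed)
            morans.append(moran_i(y - design_matrix @ np.array([1.0, 2.0]), W))
        assert all(m > 0 for m in morans)
        assert np.mean(morans) > 0.3

    def test_lambda_outside_bounds_rejected(self, hex_world, design_matrix):
        _, W = hex_world
        with pytest.raises(SpatialStatsError):
            simulate_sar_response(design_matrix, W, (1.0, 2.0), 1.5, 1.0, seed=1)
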