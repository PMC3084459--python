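"""KRR, RVR/ARD, evidence optimization, and weight-map reconstruction."""

import numpy as np
import pytest
from scipy.optimize import minimize

from fmridecode import (
    KernelMatrix,
    build_dct_basis,
    detrend_kernel,
    fit_krr,
    fit_rvr,
    linear_kernel,
    optimize_evidence,
    predict_kernel_model,
    sparsity,
    weight_map,
)
from fmridecode.regression import _rvr_log_evidence

from conftest import make_tsm


class TestKRR:
    def test_identity_kernel_closed_form(self, rng):
        t = rng.normal(size=5)
        model = fit_krr(KernelMatrix(np.eye(5)), t, lam=1.0)
        np.testing.assert_allclose(model.beta, t / 2.0, atol=1e-12)

    def test_dual_equals_primal_ridge(self, rng):
        # N=6, D=3: predictions from (X^T X + lam I)^-1 X^T t and from the
        # dual solve must coincide
        X = rng.normal(size=(6, 3))
        t = rng.normal(size=6)
        lam = 0.7
        w = np.linalg.solve(X.T @ X + lam * np.eye(3), X.T @ t)
        model = fit_krr(KernelMatrix(X @ X.T), t, lam)
        X_test = rng.normal(size=(4, 3))
        np.testing.assert_allclose(
            X_test @ w, (X_test @ X.T) @ model.beta, atol=1e-8
        )

    def test_residual_invariant(self, rng):
        tsm = make_tsm(rng, 20, 8)
        K = linear_kernel(tsm)
        t = rng.normal(size=20)
        model = fit_krr(K, t, lam=3.0)
        resid = (K.values + 3.0 * np.eye(20)) @ model.beta - t
        assert np.abs(resid).max() < 1e-8 * np.abs(t).max()

    def test_huge_lambda_dominance_bound(self, rng):
        t = rng.normal(size=10)
        K = linear_kernel(make_tsm(rng, 10, 4))
        lam = 1e12
        model = fit_krr(K, t, lam)
        assert np.linalg.norm(model.beta) <= np.linalg.norm(t) / lam * (1 + 1e-6)

    def test_singular_kernel_at_zero_lambda(self, rng):
        K = KernelMatrix(np.zeros((4, 4)))
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            fit_krr(K, rng.normal(size=4), lam=0.0)

    def test_interpolates_training_scans_at_zero_lambda(self, rng):
        X = rng.normal(size=(5, 8))  # N < D: K invertible a.s.
        t = rng.normal(size=5)
        K = KernelMatrix(X @ X.T)
        model = fit_krr(K, t, lam=0.0)
        pred = predict_kernel_model(model, KernelMatrix(K.values[[2], :]))
        assert abs(pred[0] - t[2]) < 1e-8

    def test_solution_continuous_in_lambda(self, rng):
        K = linear_kernel(make_tsm(rng, 15, 6))
        t = rng.normal(size=15)
        b1 = fit_krr(K, t, 10.0).beta
        b2 = fit_krr(K, t, 10.0 + 1e-9).beta
        assert np.abs(b1 - b2).max() < 1e-8

    def test_map_equivalence(self, rng):
        # MAP with prior precision alpha, noise sigma^2 == ridge lam=alpha*sigma^2
        X = rng.normal(size=(8, 3))
        t = rng.normal(size=8)
        alpha, sigma2 = 2.5, 0.4
        w_map = np.linalg.solve(
            X.T @ X / sigma2 + alpha * np.eye(3), X.T @ t / sigma2
        )
        w_ridge = np.linalg.solve(
            X.T @ X + alpha * sigma2 * np.eye(3), X.T @ t
        )
        np.testing.assert_allclose(w_map, w_ridge, atol=1e-8)


class TestPredict:
    def test_matches_summation_oracle(self, rng):
        K_test_train = KernelMatrix(rng.normal(size=(3, 6)))
        beta = rng.normal(size=6)
        model = fit_krr(KernelMatrix(np.eye(6)), np.zeros(6), 1.0)
        model.beta = beta
        pred = predict_kernel_model(model, K_test_train)
        for j in range(3):
            assert abs(pred[j] - sum(beta[i] * K_test_train.values[j, i] for i in range(6))) < 1e-10

    def test_column_mismatch_rejected(self, rng):
        model = fit_krr(KernelMatrix(np.eye(6)), rng.normal(size=6), 1.0)
        with pytest.raises(ValueError):
            predict_kernel_model(model, KernelMatrix(np.zeros((3, 5))))


class TestRVR:
    def test_recovers_constructed_sparse_truth(self, rng):
        # target built from the bias plus one kernel column, no noise
        X = rng.normal(size=(50, 20))
        K = KernelMatrix(X @ X.T)
        t = 0.5 + 2.0 * K.values[:, 7]
        model = fit_rvr(K, t)
        assert set(model.relevant_idx) <= {0, 8}  # bias and design column of scan 7
        pred = predict_kernel_model(model, K)
        assert np.abs(pred - t).max() < 1e-6
        assert sparsity(model) <= 0.1

    def test_fixed_point_matches_numeric_evidence_maximum(self):
        # well-posed N=5 toy: EM must match a global multistart simplex
        # maximization of the marginal likelihood over (alpha, sigma^2)
        data_rng = np.random.default_rng(3)
        X = data_rng.normal(size=(5, 3))
        K = KernelMatrix(X @ X.T)
        t = 1.0 + K.values[:, 2] + 0.1 * data_rng.normal(size=5)
        model = fit_rvr(K, t)
        Phi = np.column_stack([np.ones(5), K.values])

        def neg_ev(p):
            try:
                return -_rvr_log_evidence(
                    Phi, np.exp(np.clip(p[:6], -45, 45)),
                    float(np.exp(np.clip(p[6], -30, 30))), t,
                )
            except Exception:
                return 1e10

        x_em = np.concatenate(
            [np.log(np.clip(model.alpha, 1e-30, 1e30)), [np.log(model.sigma2)]]
        )
        best = neg_ev(x_em)
        search_rng = np.random.default_rng(99)
        for _ in range(15):
            res = minimize(
                neg_ev, search_rng.normal(0, 3, size=7), method="Nelder-Mead",
                options={"maxiter": 2000, "fatol": 1e-12, "xatol": 1e-10},
            )
            best = min(best, res.fun)
        assert -best - model.log_evidence < 1e-4

    def test_evidence_monotone_along_iterations(self, rng):
        K = linear_kernel(make_tsm(rng, 30, 10))
        t = rng.normal(size=30)
        model = fit_rvr(K, t)
        diffs = np.diff(model.log_evidence_path)
        assert np.all(diffs >= -1e-8)

    def test_bias_only_model_predicts_constant(self, rng):
        # constant target: everything except the bias gets pruned
        K = linear_kernel(make_tsm(rng, 20, 5))
        t = np.full(20, 0.7) + rng.normal(0, 1e-4, 20)
        model = fit_rvr(K, t)
        pred = predict_kernel_model(model, K)
        assert np.ptp(pred) < 0.05
        assert 0 in model.relevant_idx

    def test_pruned_weights_exactly_zero(self, rng):
        X = rng.normal(size=(40, 10))
        K = KernelMatrix(X @ X.T)
        t = K.values[:, 3] + 0.01 * rng.normal(size=40)
        model = fit_rvr(K, t)
        pruned = np.setdiff1d(np.arange(41), model.relevant_idx)
        assert np.all(model.mu[pruned] == 0.0)
        assert np.all(np.isinf(model.alpha[pruned]))

    def test_sparsity_bounds(self, rng):
        X = rng.normal(size=(50, 20))
        K = KernelMatrix(X @ X.T)
        model = fit_rvr(K, 1.0 + K.values[:, 2])
        assert 0.0 <= sparsity(model) <= 1.0


class TestEvidenceOptimizer:
    def test_recovers_known_hyperparameter_ratio(self, rng):
        # t ~ N(0, 2I + 3K) for a fixed full-rank kernel: the implied
        # lambda should concentrate near 2/3
        X = rng.normal(size=(200, 400))
        K = X @ X.T / 400
        L = np.linalg.cholesky(2.0 * np.eye(200) + 3.0 * K)
        lams = []
        for rep in range(50):
            t = L @ rng.normal(size=200)
            hp = optimize_evidence(KernelMatrix(K), t, seed=rep)
            lams.append(hp.ridge_lambda)
        ratio = np.median(lams) / (2.0 / 3.0)
        assert 0.4 <= ratio <= 1.1

    def test_zero_target_rejected(self, rng):
        K = linear_kernel(make_tsm(rng, 10, 4))
        with pytest.raises(ValueError):
            optimize_evidence(K, np.zeros(10))

    def test_constant_term_helps_offset_targets(self, rng):
        X = rng.normal(size=(60, 10))
        K = KernelMatrix(X @ X.T)
        t = 50.0 + rng.normal(size=60)  # large offset
        with_const = optimize_evidence(K, t, include_constant=True, seed=0)
        without = optimize_evidence(K, t, include_constant=False, seed=0)
        assert with_const.log_evidence > without.log_evidence

    def test_implied_lambda_positive_finite(self, rng):
        K = linear_kernel(make_tsm(rng, 40, 10))
        t = rng.normal(size=40)
        hp = optimize_evidence(K, t, seed=0)
        assert np.isfinite(hp.ridge_lambda) and hp.ridge_lambda > 0


class TestWeightMap:
    def test_unit_beta_returns_scan_pattern(self, rng):
        tsm = make_tsm(rng, 6, 5)
        beta = np.zeros(6)
        beta[2] = 1.0
        wmap = weight_map(tsm, beta)
        np.testing.assert_allclose(
            wmap[tsm.voxel_index[:, 0], 0, 0], tsm.X[2], atol=1e-12
        )

    def test_prediction_identity(self, rng):
        # w^T (R x_j) must reproduce the kernel prediction for training scans
        tsm = make_tsm(rng, 25, 12)
        drift = build_dct_basis(25, 4)
        K = detrend_kernel(linear_kernel(tsm), drift.R)
        t = rng.normal(size=25)
        model = fit_krr(K, t, lam=2.0)
        wmap = weight_map(tsm, model.beta, drift.R)
        w_vec = wmap[tsm.voxel_index[:, 0], 0, 0]
        Xbar = drift.R @ tsm.X
        np.testing.assert_allclose(Xbar @ w_vec, K.values @ model.beta, atol=1e-8)

    def test_localizes_true_blob(self):
        # KRR weight map peaks inside the active blob on synthetic data
        from fmridecode import (
            SimulationConfig,
            apply_mask,
            generate_dataset,
            smooth_volumes,
        )

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_runs=2, n_ratings=1, rating_kinds=("block",), n_active_blobs=1,
                seed=seed,
            )
            ds = generate_dataset(cfg)
            vol = smooth_volumes(ds.volumes, 6.0, cfg.voxel_size_mm)
            tsm = apply_mask(vol, ds.gm_mask, ds.run_boundaries)
            drift = build_dct_basis(tsm.n_scans, 8, ds.run_boundaries)
            K = detrend_kernel(linear_kernel(tsm), drift.R)
            model = fit_krr(K, ds.convolved_ratings[0], 100.0)
            wmap = weight_map(tsm, model.beta, drift.R)
            peak = np.unravel_index(np.argmax(np.abs(wmap)), wmap.shape)
            truth = ds.true_weight_maps[0]
            hits += truth[peak] > 0.1 * truth.max()
        assert hits >= 18

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            weight_map(make_tsm(rng, 6, 5), np.zeros(7))
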