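"""Solver contracts: objective, working response, intercept solve, fit."""

import numpy as np
import pytest
from scipy.optimize import minimize

import intlognet.solver as sv
from intlognet.data_model import (
    PenaltyConfig,
    SampleRelationLaplacian,
    StackedDesign,
    build_normalized_laplacian,
)
from intlognet.penalties import CDContext, cd_update, penalty_value
from intlognet.solver import SolverOptions

from conftest import make_logistic_data, random_graph


class TestObjective:
    def test_null_model_is_log_two(self, stacked):
        cfg = PenaltyConfig(kind="enet", lam=0.0, mu=0.0)
        val = sv.objective(
            np.zeros(stacked.n_samples), np.zeros(stacked.n_features),
            stacked, cfg,
        )
        assert val == pytest.approx(np.log(2.0), rel=1e-12)

    def test_blockwise_constant_intercepts_kill_mu_term(self, stacked):
        beta = np.zeros(stacked.n_features)
        beta0 = np.where(stacked.dataset_ids == 1, -2.0, 3.0)
        Lt = SampleRelationLaplacian(stacked.dataset_ids)
        with_mu = sv.objective(
            beta0, beta, stacked, PenaltyConfig(kind="enet", lam=0.0, mu=7.0), Ltilde=Lt
        )
        without = sv.objective(
            beta0, beta, stacked, PenaltyConfig(kind="enet", lam=0.0, mu=0.0), Ltilde=Lt
        )
        assert with_mu == pytest.approx(without, rel=1e-14)

    def test_matches_literal_term_by_term_summation(self, rng, stacked):
        beta = rng.standard_normal(stacked.n_features) * 0.5
        beta0 = rng.standard_normal(stacked.n_samples)
        cfg = PenaltyConfig(kind="enet", alpha=0.4, lam=0.3, mu=0.8)
        Lt = SampleRelationLaplacian(stacked.dataset_ids)
        # independent literal re-summation
        total = 0.0
        for i in range(stacked.n_samples):
            eta = beta0[i] + float(stacked.X[i] @ beta)
            total += -stacked.Y[i] * eta + np.log(1.0 + np.exp(eta))
        total /= stacked.n_samples
        total += cfg.lam * (
            0.5 * (1 - cfg.alpha) * float(beta @ beta) + cfg.alpha * np.abs(beta).sum()
        )
        total += cfg.mu * float(beta0 @ Lt.matrix() @ beta0)
        got = sv.objective(beta0, beta, stacked, cfg, Ltilde=Lt)
        assert got == pytest.approx(total, abs=1e-12)


class TestWorkingResponse:
    def test_zero_iterate(self, stacked):
        z, w = sv.working_response(
            np.zeros(stacked.n_samples), np.zeros(stacked.n_features), stacked
        )
        np.testing.assert_allclose(w, 0.25)
        np.testing.assert_allclose(z, np.where(stacked.Y == 1, 2.0, -2.0))

    def test_perfect_fit_returns_linear_predictor(self, rng):
        # choose beta0 so that p_i = Y-ish: use Y drawn equal to p exactly is
        # impossible for binary Y; instead check the algebraic identity
        # Z - eta == (Y - p)/w at a random iterate
        X, y, _ = make_logistic_data(rng, n=30, p=4)
        data = StackedDesign(X=X, Y=y, dataset_ids=np.ones(30, int))
        beta = rng.standard_normal(4) * 0.3
        beta0 = rng.standard_normal(30) * 0.2
        z, w = sv.working_response(beta0, beta, data)
        eta = beta0 + X @ beta
        p = 1 / (1 + np.exp(-eta))
        np.testing.assert_allclose(z - eta, (y - p) / w, rtol=1e-12)

    def test_newton_normal_equation_right_side(self, rng):
        # X~' W Z == X~' W X~ btilde_old + X~' (Y - p) for X~ = [X, I]
        X, y, _ = make_logistic_data(rng, n=15, p=3)
        data = StackedDesign(X=X, Y=y, dataset_ids=np.ones(15, int))
        beta = rng.standard_normal(3) * 0.4
        beta0 = rng.standard_normal(15) * 0.3
        z, w = sv.working_response(beta0, beta, data)
        Xt = np.hstack([X, np.eye(15)])
        btilde = np.concatenate([beta, beta0])
        p = 1 / (1 + np.exp(-(beta0 + X @ beta)))
        lhs = Xt.T @ (w * z)
        rhs = Xt.T @ (w * (Xt @ btilde)) + Xt.T @ (y - p)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestSolveBeta0:
    def test_mu_zero_identity(self, rng):
        w = rng.uniform(0.01, 0.25, 8)
        z = rng.standard_normal(8)
        xb = rng.standard_normal(8)
        Lt = SampleRelationLaplacian(np.array([1, 1, 1, 2, 2, 2, 2, 2]))
        got = sv.solve_beta0(w, z, xb, Lt, 0.0)
        np.testing.assert_allclose(got, z - xb, rtol=1e-14)

    def test_large_mu_approaches_weighted_block_means(self, rng):
        w = rng.uniform(0.01, 0.25, 10)
        z = rng.standard_normal(10) * 3
        xb = rng.standard_normal(10)
        ids = np.repeat([1, 2], 5)
        Lt = SampleRelationLaplacian(ids)
        got = sv.solve_beta0(w, z, xb, Lt, 1e8)
        s = z - xb
        for m in (1, 2):
            blk = ids == m
            wmean = np.sum(w[blk] * s[blk]) / np.sum(w[blk])
            assert np.ptp(got[blk]) < 1e-4
            np.testing.assert_allclose(got[blk], wmean, atol=1e-4)

    def test_matches_dense_linear_solve(self, rng):
        # independent oracle: assemble the full N x N system densely
        for mu in (0.05, 1.0, 17.0):
            w = rng.uniform(0.01, 0.25, 6)
            z = rng.standard_normal(6)
            xb = rng.standard_normal(6)
            Lt = SampleRelationLaplacian(np.array([1, 1, 1, 2, 2, 2]))
            got = sv.solve_beta0(w, z, xb, Lt, mu)
            N = 6
            M = np.diag(w / N) + 2 * mu * Lt.matrix()
            want = np.linalg.solve(M, w * (z - xb) / N)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_minimizes_quadratic_subproblem(self, rng):
        w = rng.uniform(0.05, 0.25, 6)
        z = rng.standard_normal(6)
        xb = rng.standard_normal(6)
        Lt = SampleRelationLaplacian(np.array([1, 1, 1, 1, 2, 2]))
        mu = 0.6
        got = sv.solve_beta0(w, z, xb, Lt, mu)

        def f(v):
            return 0.5 * np.mean(w * (z - v - xb) ** 2) + mu * Lt.quadform(v)

        res = minimize(f, np.zeros(6), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        assert f(got) <= res.fun + 1e-10

    def test_constant_mode_is_weighted_mean(self, rng):
        w = rng.uniform(0.05, 0.25, 5)
        z = rng.standard_normal(5)
        Lt = SampleRelationLaplacian(np.ones(5, int))
        got = sv.solve_beta0(w, z, np.zeros(5), Lt, 1.0, constant=True)
        np.testing.assert_allclose(got, np.sum(w * z) / np.sum(w))


def quad_objective(XF, w, z, beta, beta0, cfg, net, Lt):
    r = z - beta0 - XF @ beta
    val = 0.5 * np.mean(w * r**2) + cfg.lam * penalty_value(cfg, beta, net)
    return val + cfg.mu * Lt.quadform(beta0)


class TestInnerQuadraticSolve:
    def test_huge_lambda_zeroes_beta(self, rng):
        X, y, _ = make_logistic_data(rng, n=25, p=4)
        XF = np.asfortranarray(X)
        w = np.full(25, 0.25)
        z = np.where(y == 1, 2.0, -2.0)
        Lt = SampleRelationLaplacian(np.ones(25, int))
        cfg = PenaltyConfig(kind="lasso", lam=1e6, mu=1.0)
        beta, beta0 = sv.inner_quadratic_solve(
            XF, w, z, np.zeros(4), np.zeros(25), cfg, None, Lt, SolverOptions()
        )
        np.testing.assert_array_equal(beta, 0.0)

    def test_matches_generic_numerical_minimizer_enet(self, rng):
        n, p = 12, 3
        X, y, _ = make_logistic_data(rng, n=n, p=p)
        XF = np.asfortranarray(X)
        w = rng.uniform(0.05, 0.25, n)
        z = rng.standard_normal(n) * 2
        Lt = SampleRelationLaplacian(np.repeat([1, 2], 6))
        cfg = PenaltyConfig(kind="enet", alpha=0.5, lam=0.1, mu=0.4)
        opts = SolverOptions(tol_inner=1e-10, max_inner_sweeps=2000)
        beta, beta0 = sv.inner_quadratic_solve(
            XF, w, z, np.zeros(p), np.zeros(n), cfg, None, Lt, opts
        )
        ours = quad_objective(XF, w, z, beta, beta0, cfg, None, Lt)

        def f(v):
            return quad_objective(XF, w, z, v[:p], v[p:], cfg, None, Lt)

        x0 = np.concatenate([beta, beta0]) + 0.05 * rng.standard_normal(n + p)
        res = minimize(f, x0, method="Powell",
                       options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 100000})
        assert ours <= res.fun + 1e-6

    def test_unpenalized_matches_weighted_least_squares(self, rng):
        # single block, constant intercept, lam=0: classic WLS with intercept
        n, p = 30, 3
        X, y, _ = make_logistic_data(rng, n=n, p=p)
        XF = np.asfortranarray(X)
        w = rng.uniform(0.05, 0.25, n)
        z = rng.standard_normal(n) * 2
        Lt = SampleRelationLaplacian(np.ones(n, int))
        cfg = PenaltyConfig(kind="enet", alpha=0.5, lam=0.0, mu=1.0)
        opts = SolverOptions(tol_inner=1e-12, max_inner_sweeps=5000)
        beta, beta0 = sv.inner_quadratic_solve(
            XF, w, z, np.zeros(p), np.zeros(n), cfg, None, Lt, opts,
            constant_intercept=True,
        )
        Xt = np.hstack([np.ones((n, 1)), X])
        theta = np.linalg.solve(Xt.T @ (w[:, None] * Xt), Xt.T @ (w * z))
        np.testing.assert_allclose(beta, theta[1:], atol=1e-6)
        np.testing.assert_allclose(beta0, theta[0], atol=1e-6)


class TestFit:
    def test_matches_reference_l1_logistic_with_constant_intercept(self, rng):
        from sklearn.linear_model import LogisticRegression

        n, p, lam = 120, 8, 0.05
        X, y, beta_true = make_logistic_data(
            rng, n=n, p=p, beta=np.array([2.0, -1.5, 1.0, 0, 0, 0.5, 0, 0]),
        )
        data = StackedDesign(X=X, Y=y, dataset_ids=np.ones(n, int))
        fr = sv.fit(data, PenaltyConfig(kind="lasso", lam=lam, mu=1e6))
        sk = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="saga",
            tol=1e-12, max_iter=50000,
        ).fit(X, y)
        np.testing.assert_allclose(fr.beta, sk.coef_[0], atol=1e-3)
        assert np.ptp(fr.beta0) < 1e-4  # mu forces a constant intercept
        assert fr.dataset_intercepts[0] == pytest.approx(
            float(sk.intercept_[0]), abs=1e-3
        )

    def test_separable_data_terminates(self):
        X = np.array([[x] for x in (-3.0, -2.0, -1.0, 1.0, 2.0, 3.0)])
        y = np.array([0, 0, 0, 1, 1, 1.0])
        data = StackedDesign(X=X, Y=y, dataset_ids=np.ones(6, int))
        fr = sv.fit(data, PenaltyConfig(kind="lasso", lam=0.01, mu=1.0))
        assert np.isfinite(fr.beta).all()
        assert fr.beta[0] > 0

    @pytest.mark.parametrize("kind", ["lasso", "enet", "network", "abs_network"])
    def test_objective_trace_non_increasing(self, rng, stacked, kind):
        net = (
            build_normalized_laplacian(random_graph(rng, stacked.n_features, 0.5))
            if kind in ("network", "abs_network")
            else None
        )
        fr = sv.fit(stacked, PenaltyConfig(kind=kind, alpha=0.5, lam=0.05, mu=1.0), net=net)
        trace = np.array(fr.objective_trace)
        assert np.all(np.diff(trace) <= 1e-12)
        assert fr.converged

    @pytest.mark.parametrize("kind", ["lasso", "enet", "network", "abs_network"])
    def test_kkt_fixed_point_at_convergence(self, rng, stacked, kind):
        # at the solution, re-running the coordinate update on the final
        # working response must leave every coefficient (nearly) unchanged
        net = (
            build_normalized_laplacian(random_graph(rng, stacked.n_features, 0.5))
            if kind in ("network", "abs_network")
            else None
        )
        cfg = PenaltyConfig(kind=kind, alpha=0.5, lam=0.05, mu=1.0)
        opts = SolverOptions(tol_outer=1e-10, tol_inner=1e-8, max_outer=200)
        fr = sv.fit(stacked, cfg, net=net, options=opts)
        z, w = sv.working_response(fr.beta0, fr.beta, stacked)
        for k in range(stacked.n_features):
            ctx = CDContext(
                k=k, X=stacked.X, w=w, z=z, beta0=fr.beta0, beta=fr.beta,
                config=cfg, net=net,
            )
            assert cd_update(ctx) == pytest.approx(fr.beta[k], abs=1e-4)

    def test_permutation_invariance(self, rng, stacked):
        cfg = PenaltyConfig(kind="enet", alpha=0.5, lam=0.05, mu=1.0)
        fr = sv.fit(stacked, cfg)
        perm = rng.permutation(stacked.n_samples)
        permuted = StackedDesign(
            X=stacked.X[perm], Y=stacked.Y[perm], dataset_ids=stacked.dataset_ids[perm]
        )
        fr2 = sv.fit(permuted, cfg)
        np.testing.assert_allclose(fr2.beta, fr.beta, atol=1e-10)
        np.testing.assert_allclose(fr2.beta0, fr.beta0[perm], atol=1e-10)

    def test_mu_infinity_limit_equals_constant_intercept_model(self, stacked):
        cfg_inf = PenaltyConfig(kind="enet", alpha=0.5, lam=0.05, mu=1e7)
        fr_inf = sv.fit(stacked, cfg_inf)
        fr_const = sv.fit(
            stacked, PenaltyConfig(kind="enet", alpha=0.5, lam=0.05, mu=1.0),
            constant_intercept=True,
        )
        np.testing.assert_allclose(fr_inf.beta, fr_const.beta, atol=1e-4)
        np.testing.assert_allclose(
            fr_inf.dataset_intercepts, fr_const.dataset_intercepts, atol=1e-4
        )

    def test_mu_zero_decouples_intercepts_in_subproblem(self, rng, stacked):
        # each beta0_i absorbs its own working residual exactly, so the
        # quadratic subproblem returns beta0 = Z - X beta
        n, p = stacked.n_samples, stacked.n_features
        z, w = sv.working_response(
            rng.standard_normal(n) * 0.1, np.zeros(p), stacked
        )
        cfg = PenaltyConfig(kind="enet", alpha=0.5, lam=0.1, mu=0.0)
        Lt = SampleRelationLaplacian(stacked.dataset_ids)
        beta, beta0 = sv.inner_quadratic_solve(
            np.asfortranarray(stacked.X), w, z, np.zeros(p), np.zeros(n),
            cfg, None, Lt, SolverOptions(),
        )
        np.testing.assert_allclose(beta0, z - stacked.X @ beta, atol=1e-10)

    def test_dataset_intercepts_are_block_means(self, stacked):
        fr = sv.fit(stacked, PenaltyConfig(kind="enet", lam=0.05, mu=1.0))
        for m, val in zip(fr.dataset_labels, fr.dataset_intercepts):
            assert val == pytest.approx(
                fr.beta0[stacked.dataset_ids == m].mean(), abs=1e-12
            )

    def test_missing_network_rejected(self, stacked):
        with pytest.raises(ValueError, match="network"):
            sv.fit(stacked, PenaltyConfig(kind="network", lam=0.1))


def test_trace_tsv_export(tmp_path, stacked):
    import pandas as pd

    fr = sv.fit(stacked, PenaltyConfig(kind="enet", lam=0.05, mu=1.0))
    path = tmp_path / "trace.tsv"
    sv.write_trace_tsv(fr, path)
    log = pd.read_csv(path, sep="\t")
    assert list(log.columns) == ["iteration", "objective", "max_coef_change"]
    np.testing.assert_allclose(log["objective"], fr.objective_trace, rtol=1e-9)
    assert len(log) == len(fr.objective_trace)
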