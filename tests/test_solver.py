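"""Coordinate-descent solver: descent, convergence, regimes, variance sweep."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.linalg import block_diag
from scipy.stats import multivariate_normal

from hdlmm.data import ClusteredData
from hdlmm.likelihood import ModelParams, VarParams, neg_log_likelihood
from hdlmm.penalties import PenaltySpec, penalty_total
from hdlmm.solver import (
    SolverControl,
    convergence_check,
    fit_once,
    update_variance_param,
)

from conftest import random_clustered


def objective_at(beta, var, data, spec):
    params = ModelParams(beta, var)
    return neg_log_likelihood(params, data) + penalty_total(
        beta, data.penalized_mask(), spec
    )


class TestConvergenceCheck:
    def test_identical_params_converged(self, rng):
        _, params = random_clustered(rng)
        ctrl = SolverControl()
        assert convergence_check(params, params, 10.0, 10.0, ctrl)

    def test_large_objective_change_not_converged(self, rng):
        _, params = random_clustered(rng)
        ctrl = SolverControl(tol=1e-4)
        assert not convergence_check(params, params, 10.0, 10.0 + 10 * 1e-4 * 11, ctrl)

    def test_refit_from_solution_is_fixed_point(self, rng):
        data, _ = random_clustered(rng, g=4, n_i=6, p=5, q=1)
        spec = PenaltySpec("lasso", 0.5)
        fit = fit_once(data, spec, "scalar", control=SolverControl(tol=1e-8))
        refit = fit_once(data, spec, "scalar", init=fit.params,
                         control=SolverControl(tol=1e-8))
        assert refit.converged
        assert refit.n_iter <= 3
        np.testing.assert_allclose(refit.params.beta, fit.params.beta, atol=1e-4)


class TestVarianceUpdate:
    def test_sigma2_profile_closed_form(self, rng):
        # with Psi = 0 and beta fixed the sigma2 minimizer is RSS / N
        data, params = random_clustered(rng, g=3, n_i=5, p=4, q=1)
        params0 = ModelParams(params.beta, VarParams("scalar", [0.0], 1.0, q=1))
        r = data.y - data.X @ params.beta
        expected = float(r @ r) / data.n_obs
        got = update_variance_param(params0.var.n_params, params0, data)
        assert got == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("structure,q,j", [("scalar", 1, 0),
                                               ("diagonal", 2, 1),
                                               ("unstructured", 2, 1)])
    def test_matches_grid_scan(self, rng, structure, q, j):
        data, params = random_clustered(rng, g=4, n_i=4, p=4, q=q,
                                        structure=structure)
        got = update_variance_param(j, params, data)
        lo = 0.0 if params.var.diag_param_mask()[j] else -4.0
        grid = np.linspace(lo, 4.0, 10_001)
        vals = [
            neg_log_likelihood(
                ModelParams(params.beta, params.var.with_theta_entry(j, v)), data
            )
            for v in grid
        ]
        best = grid[int(np.argmin(vals))]
        assert got == pytest.approx(best, abs=2 * (grid[1] - grid[0]))

    def test_symmetric_instance_off_diagonal_near_zero(self, rng):
        # data generated with diagonal Psi: the unconstrained off-diagonal
        # Cholesky entry of an unstructured model should sit near zero
        data, params = random_clustered(
            rng, g=40, n_i=6, p=3, q=2, structure="diagonal", theta_scale=1.0
        )
        var_u = VarParams("unstructured",
                          [params.var.theta[0], 0.0, params.var.theta[1]],
                          params.var.sigma2, q=2)
        params_u = ModelParams(params.beta, var_u)
        got = update_variance_param(1, params_u, data)  # the (2,1) entry of L
        assert abs(got) < 0.5

    def test_index_out_of_range(self, rng):
        data, params = random_clustered(rng)
        with pytest.raises(IndexError):
            update_variance_param(5, params, data)


class TestFitOnce:
    def test_lam_above_bracket_zeroes_all_penalized(self, rng):
        data, _ = random_clustered(rng, g=4, n_i=5, p=8, q=1)
        for family in ("lasso", "scad"):
            fit = fit_once(data, PenaltySpec(family, 1e4), "scalar")
            assert fit.converged
            assert not np.any(fit.params.beta[data.penalized_mask()])

    def test_interpolation_flagged_when_p_exceeds_n(self, rng):
        # p > N with lam ~ 0: residuals -> 0 and sigma2 -> 0
        data, _ = random_clustered(rng, g=3, n_i=4, p=30, q=1)
        fit = fit_once(data, PenaltySpec("lasso", 1e-4), "scalar",
                       control=SolverControl(max_iter=300))
        assert fit.diverged_interpolating
        assert not fit.converged
        assert not np.isfinite(fit.objective)
        assert fit.params.var.sigma2 < 1e-3 * np.var(data.y)
        # the marginal fit interpolates: the random intercept absorbs the
        # per-cluster residual means, so center residuals within clusters
        resid = data.y - data.X @ fit.params.beta
        for idx in data.cluster_indices:
            resid[idx] -= resid[idx].mean()
        assert float(resid @ resid) < 1e-2 * float(data.y @ data.y)

    def test_classical_limit_matches_dense_ml_oracle(self, rng):
        # lam = 0, p = 5 << N = 60, q = 1: compare against a generic
        # optimizer on the dense stacked negative log-density
        data, _ = random_clustered(rng, g=10, n_i=6, p=5, q=1, sigma2=0.5)
        fit = fit_once(data, PenaltySpec("lasso", 0.0), "scalar",
                       control=SolverControl(tol=1e-10, max_iter=500))

        def dense_nll(x):
            beta, log_th, log_s2 = x[:5], x[5], x[6]
            psi = np.exp(2 * log_th)
            blocks = [
                data.Z[idx] @ (psi * np.eye(1)) @ data.Z[idx].T
                + np.exp(log_s2) * np.eye(len(idx))
                for idx in data.cluster_indices
            ]
            V = block_diag(*blocks)
            return -multivariate_normal.logpdf(data.y, data.X @ beta, V)

        x0 = np.concatenate([np.zeros(5), [0.0, 0.0]])
        res = minimize(dense_nll, x0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10,
                                "fatol": 1e-12})
        beta_star = res.x[:5]
        psi_star = np.exp(2 * res.x[5])
        s2_star = np.exp(res.x[6])
        np.testing.assert_allclose(fit.params.beta, beta_star, rtol=1e-3,
                                   atol=1e-3)
        assert fit.params.var.sigma2 == pytest.approx(s2_star, rel=1e-3)
        assert fit.params.var.theta[0] ** 2 == pytest.approx(psi_star, rel=5e-3,
                                                             abs=1e-3)

    def test_lasso_objective_monotone_along_trace(self):
        master = np.random.default_rng(11)
        for _ in range(20):
            data, _ = random_clustered(master, g=3, n_i=5,
                                       p=int(master.integers(4, 12)), q=1)
            fit = fit_once(data, PenaltySpec("lasso", 0.8), "scalar")
            objs = [h["objective"] for h in fit.active_history]
            assert all(a >= b - 1e-10 for a, b in zip(objs, objs[1:]))

    def test_lasso_solution_is_coordinatewise_minimum(self, rng):
        data, _ = random_clustered(rng, g=4, n_i=6, p=6, q=1)
        spec = PenaltySpec("lasso", 0.6)
        fit = fit_once(data, spec, "scalar", control=SolverControl(tol=1e-10))
        q0 = objective_at(fit.params.beta, fit.params.var, data, spec)
        for j in range(data.n_fixed):
            for eps in (-0.02, -0.002, 0.002, 0.02):
                beta = fit.params.beta.copy()
                beta[j] += eps
                assert objective_at(beta, fit.params.var, data, spec) >= q0 - 1e-7

    def test_cluster_order_permutation_invariance(self, rng):
        data, _ = random_clustered(rng, g=4, n_i=5, p=6, q=1)
        order = np.concatenate([data.cluster_indices[i] for i in [2, 0, 3, 1]])
        data2 = ClusteredData(X=data.X[order], Z=data.Z[order],
                              y=data.y[order], groups=data.groups[order],
                              nonpen=data.nonpen)
        spec = PenaltySpec("scad", 0.7)
        f1 = fit_once(data, spec, "scalar", control=SolverControl(tol=1e-8))
        f2 = fit_once(data2, spec, "scalar", control=SolverControl(tol=1e-8))
        np.testing.assert_allclose(f1.params.beta, f2.params.beta, atol=1e-6)
        assert f1.params.var.sigma2 == pytest.approx(f2.params.var.sigma2,
                                                     rel=1e-5)

    def test_penalized_column_storage_order_invariance(self, rng):
        data, _ = random_clustered(rng, g=4, n_i=5, p=7, q=1)
        perm_pen = np.concatenate([[0], 1 + rng.permutation(6)])
        data2 = ClusteredData(X=data.X[:, perm_pen], Z=data.Z, y=data.y,
                              groups=data.groups, nonpen={0})
        # LASSO: the beta-subproblem is convex, so the solution should not
        # depend on the storage order of the penalized columns
        spec = PenaltySpec("lasso", 0.5)
        f1 = fit_once(data, spec, "scalar", control=SolverControl(tol=1e-9))
        f2 = fit_once(data2, spec, "scalar", control=SolverControl(tol=1e-9))
        np.testing.assert_allclose(f1.params.beta[perm_pen], f2.params.beta,
                                   atol=2e-4)

    def test_max_iter_warns_not_raises(self, rng):
        data, _ = random_clustered(rng, g=3, n_i=5, p=6, q=1)
        with pytest.warns(RuntimeWarning, match="max_iter"):
            fit = fit_once(data, PenaltySpec("lasso", 0.5), "scalar",
                           control=SolverControl(tol=1e-15, max_iter=3))
        assert not fit.converged
        assert fit.n_iter == 3

    def test_zeroed_coefficients_can_reenter_on_full_sweeps(self, rng):
        # a signal strong enough to re-enter must appear in the solution
        # even though early active-set sweeps exclude it from updates
        data, _ = random_clustered(rng, g=5, n_i=6, p=10, q=1)
        beta_sig = np.zeros(10)
        beta_sig[4] = 5.0
        y = data.X @ beta_sig + 0.2 * rng.standard_normal(data.n_obs)
        data = ClusteredData(X=data.X, Z=data.Z, y=y, groups=data.groups,
                             nonpen=data.nonpen)
        fit = fit_once(data, PenaltySpec("scad", 1.0), "scalar")
        assert fit.params.beta[4] != 0.0
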