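"""Solver correctness: KKT certificates, oracle equivalence, path shape."""

import numpy as np
import pytest
from sklearn.base import clone

import lawnscreen as ls
from lawnscreen.inference import (SUPPORT_REL_TOL, SparsitySweep,
                                  WeightSolution, kkt_violation)


def random_instance(rng, max_cols=10):
    n = int(rng.integers(4, 13))
    p = int(rng.integers(2, max_cols + 1))
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    lam = 10.0 ** rng.uniform(-4, 1)
    return X, y, lam


class TestLassoSolve:
    def test_above_lambda_max_gives_zero(self, planted_screen):
        M, _truth, _table, P = planted_screen
        lam0 = ls.lam_max(M, P)
        sol = ls.lasso_solve(M, P, lam0 * 1.01)
        assert not sol.weights.any()
        assert len(sol.support) == 0

    def test_lam_zero_square_system_is_exact(self, rng):
        X = rng.normal(size=(5, 5)) + 5 * np.eye(5)
        y = rng.normal(size=5)
        sol = ls.lasso_solve(X, y, 0.0)
        assert np.allclose(X @ sol.weights, y, atol=1e-8)
        assert sol.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_kkt_certificate_on_random_instances(self, rng):
        for _ in range(30):
            X, y, lam = random_instance(rng)
            sol = ls.lasso_solve(X, y, lam)
            assert kkt_violation(X, y, sol.weights, lam) <= 1e-6

    def test_matches_brute_force_oracle(self, rng):
        worst = 0.0
        for _ in range(40):
            X, y, lam = random_instance(rng)
            a = ls.lasso_solve(X, y, lam)
            b = ls.brute_force_solve(X, y, lam)
            worst = max(worst, float(np.max(np.abs(a.weights - b.weights))))
        assert worst <= 1e-5

    def test_scale_equivariance(self, planted_screen):
        M, _truth, _table, P = planted_screen
        base = ls.lasso_solve(M.values, P.values, 0.3)
        scaled = ls.lasso_solve(M.values, 2.5 * P.values, 2.5 * 0.3)
        assert np.allclose(scaled.weights, 2.5 * base.weights, atol=1e-6)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="shapes"):
            ls.lasso_solve(rng.normal(size=(4, 3)), rng.normal(size=5), 0.1)


class TestBruteForce:
    def test_huge_lambda_gives_zero(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        sol = ls.brute_force_solve(X, y, 1e6)
        assert not sol.weights.any()

    def test_lam_zero_overdetermined_is_ols(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        sol = ls.brute_force_solve(X, y, 0.0)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(sol.weights, ols)

    def test_column_limit(self, rng):
        with pytest.raises(ValueError, match="columns"):
            ls.brute_force_solve(rng.normal(size=(5, 15)),
                                 rng.normal(size=5), 0.1)


class TestSweepAndElbow:
    def test_path_monotonicity(self, planted_screen):
        M, _truth, _table, P = planted_screen
        sweep = ls.sparsity_sweep(M, P, n_points=60)
        chi2, l1 = sweep.chi2, sweep.l1_norms
        assert (np.diff(chi2) >= -1e-9 * max(chi2.max(), 1)).all()
        assert (np.diff(l1) <= 1e-9 * max(l1.max(), 1)).all()

    def test_grid_spans_six_orders(self, planted_screen):
        M, _truth, _table, P = planted_screen
        sweep = ls.sparsity_sweep(M, P)
        assert sweep.lam_grid[-1] / sweep.lam_grid[0] == pytest.approx(1e6, rel=0.01)

    def test_flat_chi2_selects_largest_lambda(self):
        sols = tuple(WeightSolution(weights=np.zeros(3), lam=l, chi2=1.0,
                                    support=np.array([], dtype=int))
                     for l in (0.1, 1.0, 10.0))
        sweep = SparsitySweep(lam_grid=np.array([0.1, 1.0, 10.0]),
                              solutions=sols)
        lam, _sol = ls.select_elbow(sweep)
        assert lam == 10.0

    def test_step_increase_selects_point_below_step(self):
        chi2s = [1.0, 1.0, 1.0, 50.0, 100.0]
        sols = tuple(WeightSolution(weights=np.zeros(2), lam=l, chi2=c,
                                    support=np.array([], dtype=int))
                     for l, c in zip([0.1, 0.3, 1.0, 3.0, 10.0], chi2s))
        sweep = SparsitySweep(lam_grid=np.array([0.1, 0.3, 1.0, 3.0, 10.0]),
                              solutions=sols)
        lam, _sol = ls.select_elbow(sweep)
        assert lam == 1.0

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            ls.select_elbow(SparsitySweep(lam_grid=np.array([]), solutions=()))

    def test_noiseless_planted_support_interval_exists(self, fixture_matrix):
        # an interval of penalties recovers exactly the planted support
        M = fixture_matrix
        truth = ls.plant_ground_truth(M, 4, 20, 60, 0.0, seed=1003)
        P = M.values @ truth.w_reentry
        sweep = ls.sparsity_sweep(M.values, P)
        planted = set(truth.support("reentry_latency").tolist())
        exact = [set(s.support.tolist()) == planted for s in sweep.solutions]
        assert sum(exact) >= 3

    def test_elbow_recovers_planted_support_noiseless(self, fixture_matrix):
        M = fixture_matrix
        truth = ls.plant_ground_truth(M, 4, 20, 60, 0.0, seed=1003)
        est = ls.ElbowScreenLasso().fit(M.values, M.values @ truth.w_reentry)
        assert set(est.support_.tolist()) == set(
            truth.support("reentry_latency").tolist())

    def test_reduced_system_elbow_agrees_with_brute_force(self, rng):
        # 10-column subsystem: elbow solution equals the exact minimizer
        X = (rng.random((8, 10)) < 0.3).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1.0
        w0 = np.zeros(10)
        w0[[2, 7]] = [3.0, 5.0]
        y = X @ w0
        est = ls.ElbowScreenLasso().fit(X, y)
        exact = ls.brute_force_solve(X, y, est.lam_)
        assert np.allclose(est.coef_, exact.weights, atol=1e-5)


class TestEstimatorApi:
    def test_sklearn_clone_and_params(self):
        est = ls.ElbowScreenLasso(n_points=30, rel_tol=0.002)
        cl = clone(est)
        assert cl.get_params()["n_points"] == 30
        est.set_params(rel_tol=0.01)
        assert est.rel_tol == 0.01

    def test_predict_reproduces_gated_phenotypes(self, planted_screen):
        M, _truth, _table, P = planted_screen
        est = ls.ElbowScreenLasso().fit(M, P)
        pred = est.predict(M)
        # at the elbow the fit explains the phenotype up to noise scale
        assert np.mean((pred - P.values) ** 2) <= 0.05 * np.mean(P.values ** 2)


class TestBootstrap:
    def test_zero_noise_collapses_intervals(self, fixture_matrix):
        M = fixture_matrix
        truth = ls.plant_ground_truth(M, 3, 10, 20, 0.0, seed=5)
        table = ls.simulate_phenotypes(M, truth, n_reps=3, seed=0)
        est = ls.ElbowScreenLasso().fit(
            M, ls.build_phenotype_vector(
                ls.phenotypes_from_table(table, "reentry_latency"),
                "reentry_latency", line_order=M.line_ids))
        rep = ls.bootstrap_weights(M, table, "reentry_latency", 0.05,
                                   lam=est.lam_, n_boot=50, seed=1)
        assert np.allclose(rep.hi - rep.lo, 0.0)
        assert set(rep.selection_frequency.tolist()) <= {0.0, 1.0}

    def test_deterministic_given_seed(self, planted_screen):
        M, _truth, table, _P = planted_screen
        a = ls.bootstrap_weights(M, table, "reentry_latency", 0.05, lam=0.1,
                                 n_boot=40, seed=9)
        b = ls.bootstrap_weights(M, table, "reentry_latency", 0.05, lam=0.1,
                                 n_boot=40, seed=9)
        assert np.array_equal(a.median, b.median)
        assert np.array_equal(a.selection_frequency, b.selection_frequency)

    def test_planted_neurons_dominate_selection(self, planted_screen):
        M, truth, table, P = planted_screen
        est = ls.ElbowScreenLasso().fit(M, P)
        rep = ls.bootstrap_weights(M, table, "reentry_latency", 0.05,
                                   lam=est.lam_, n_boot=300, seed=3)
        planted = truth.support("reentry_latency")
        assert rep.selection_frequency[planted].min() >= 0.9
        others = np.delete(np.abs(rep.median), planted)
        assert others.max() <= 0.2 * np.abs(rep.median).max()

    def test_requires_two_replicates(self, fixture_matrix):
        M = fixture_matrix
        truth = ls.plant_ground_truth(M, 1, 1, 2, 0.1, seed=0)
        table = ls.simulate_phenotypes(M, truth, n_reps=1, seed=0)
        with pytest.raises(ValueError, match="replicates"):
            ls.bootstrap_weights(M, table, "reentry_latency", 0.05, lam=0.1,
                                 n_boot=10, seed=0)
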