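"""Linear ε-SVR: dual-QP oracle agreement, KKT structure, grid search."""

import numpy as np
import pytest
from scipy.optimize import minimize

import chemocal as cc
from chemocal.errors import ParameterError


def _qp_oracle(X, y, epsilon, cost):
    """Brute-force ε-SVR dual via a generic solver on the 2n-variable QP."""
    n = X.shape[0]
    K = X @ X.T

    def objective(z):
        a, a_star = z[:n], z[n:]
        d = a - a_star
        return 0.5 * d @ K @ d + epsilon * np.sum(a + a_star) - y @ d

    res = minimize(
        objective,
        np.zeros(2 * n),
        method="SLSQP",
        bounds=[(0.0, cost)] * (2 * n),
        constraints=[{"type": "eq", "fun": lambda z: np.sum(z[:n]) - np.sum(z[n:])}],
        options={"ftol": 1e-14, "maxiter": 5000},
    )
    assert res.success
    return res.x[:n] - res.x[n:]


@pytest.fixture()
def small_problem(rng):
    X = rng.normal(size=(5, 2))
    X -= X.mean(axis=0)
    y = X @ np.array([1.5, -0.7]) + rng.normal(0, 0.3, 5)
    y -= y.mean()
    return X, y


class TestTrainLinearSVR:
    def test_flat_targets_inside_tube(self, rng):
        X = rng.normal(size=(5, 3))
        y = np.full(5, 3.0)
        model = cc.train_linear_svr(X, y, epsilon=0.1, cost=1.0)
        assert model.support_indices.size == 0
        assert np.abs(model.weight_vector).max() < 1e-12
        assert model.bias == pytest.approx(3.0, abs=1e-9)
        np.testing.assert_allclose(cc.predict_svr(model, X), 3.0, atol=1e-9)

    def test_matches_brute_force_qp_oracle(self, small_problem):
        X, y = small_problem
        model = cc.train_linear_svr(X, y, epsilon=0.1, cost=1.0)
        beta_oracle = _qp_oracle(X, y, 0.1, 1.0)
        np.testing.assert_allclose(model.dual_coefficients, beta_oracle, atol=1e-6)

    def test_equality_constraint_and_box(self, small_problem):
        X, y = small_problem
        for cost in (0.5, 5.0):
            model = cc.train_linear_svr(X, y, epsilon=0.05, cost=cost)
            beta = model.dual_coefficients
            assert abs(beta.sum()) < 1e-8 * cost
            assert np.all(np.abs(beta) <= cost * (1 + 1e-12))

    def test_kkt_structure(self, small_problem):
        X, y = small_problem
        eps, cost = 0.15, 2.0
        model = cc.train_linear_svr(X, y, eps, cost)
        pred = X @ model.weight_vector + model.bias
        resid = np.abs(y - pred)
        beta = model.dual_coefficients
        free = (np.abs(beta) > 1e-8 * cost) & (np.abs(beta) < cost * (1 - 1e-8))
        # free support vectors sit on the tube boundary
        assert np.all(np.abs(resid[free] - eps) < 1e-5)
        # samples strictly inside the tube carry zero coefficients
        inside = resid < eps - 1e-6
        assert np.all(np.abs(beta[inside]) < 1e-8 * cost)

    def test_predicting_free_support_vector_hits_tube_boundary(self, small_problem):
        X, y = small_problem
        model = cc.train_linear_svr(X, y, 0.15, 2.0)
        beta = model.dual_coefficients
        free = np.flatnonzero(
            (np.abs(beta) > 1e-8 * 2.0) & (np.abs(beta) < 2.0 * (1 - 1e-8))
        )
        pred = cc.predict_svr(model, X)
        for i in free:
            assert abs(abs(y[i] - pred[i]) - 0.15) < 1e-6

    def test_exactly_linear_data_stays_inside_tube(self, rng):
        X = rng.normal(size=(8, 3))
        X -= X.mean(axis=0)
        beta_true = np.array([2.0, -1.0, 0.5])
        y = X @ beta_true
        model = cc.train_linear_svr(X, y, epsilon=0.25, cost=100.0)
        resid = np.abs(y - cc.predict_svr(model, X))
        assert np.all(resid <= 0.25 + 1e-8)

    def test_prediction_equals_explicit_weight_form(self, small_problem, rng):
        X, y = small_problem
        model = cc.train_linear_svr(X, y, 0.1, 1.0)
        X_new = rng.normal(size=(4, 2))
        np.testing.assert_allclose(
            cc.predict_svr(model, X_new),
            X_new @ model.weight_vector + model.bias,
            atol=1e-10,
        )

    @pytest.mark.parametrize("seed", [1, 4, 9])
    def test_growing_tube_sheds_support_vectors(self, seed):
        # the typical sparsification of the ε-tube, checked on fixtures where
        # the count is strictly well-ordered (it is not a universal theorem)
        r = np.random.default_rng(seed)
        X = r.normal(size=(5, 2))
        X -= X.mean(axis=0)
        y = X @ np.array([1.5, -0.7]) + r.normal(0, 0.3, 5)
        y -= y.mean()
        counts = [
            cc.train_linear_svr(X, y, eps, 2.0).support_indices.size
            for eps in (0.01, 0.05, 0.1, 0.2, 0.5, 1.0)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_parameter_validation(self, small_problem):
        X, y = small_problem
        with pytest.raises(ParameterError):
            cc.train_linear_svr(X, y, epsilon=-0.1, cost=1.0)
        with pytest.raises(ParameterError):
            cc.train_linear_svr(X, y, epsilon=0.1, cost=0.0)

    def test_primal_dual_objectives_agree(self, small_problem):
        X, y = small_problem
        eps, cost = 0.1, 3.0
        model = cc.train_linear_svr(X, y, eps, cost)
        beta = model.dual_coefficients
        w = model.weight_vector
        K = X @ X.T
        primal = 0.5 * w @ w + cost * np.sum(
            np.maximum(0.0, np.abs(y - (X @ w + model.bias)) - eps)
        )
        dual = -(0.5 * beta @ K @ beta - y @ beta + eps * np.abs(beta).sum())
        assert primal - dual <= 1e-6 * (1 + abs(dual))
        assert primal - dual >= -1e-9 * (1 + abs(dual))  # weak duality


class TestGridSearch:
    def test_single_candidate_returned(self, noisy_train, train_design):
        y = train_design.column("PR")
        gs = cc.grid_search_svr(noisy_train, y, [0.1], [50.0], k=4, seed=0)
        assert (gs.best_epsilon, gs.best_cost) == (0.1, 50.0)
        assert len(gs.grid) == 1

    def test_selected_pair_attains_grid_minimum_with_tie_rule(
        self, noisy_train, train_design
    ):
        y = train_design.column("PR")
        gs = cc.grid_search_svr(
            noisy_train, y, [0.05, 0.2, 0.6], [30.0, 100.0, 500.0], k=4, seed=1
        )
        grid = gs.grid
        m = grid["rmsecv"].min()
        ties = grid[grid["rmsecv"] <= m + 1e-9]
        expected = ties.sort_values(["cost", "epsilon"]).iloc[0]
        assert gs.best_cost == expected["cost"]
        assert gs.best_epsilon == expected["epsilon"]
        assert gs.best_rmsecv <= m + 1e-9

    def test_seeded_reruns_identical(self, noisy_train, train_design):
        y = train_design.column("PR")
        args = (noisy_train, y, [0.1, 0.3], [30.0, 100.0])
        a = cc.grid_search_svr(*args, k=4, seed=7)
        b = cc.grid_search_svr(*args, k=4, seed=7)
        assert a.grid.equals(b.grid)
        assert (a.best_epsilon, a.best_cost) == (b.best_epsilon, b.best_cost)

    def test_parameter_validation(self, noisy_train, train_design):
        y = train_design.column("PR")
        with pytest.raises(ParameterError):
            cc.grid_search_svr(noisy_train, y, [], [30.0], k=4, seed=0)
        with pytest.raises(ParameterError):
            cc.grid_search_svr(noisy_train, y, [0.1], [30.0], k=17, seed=0)

    def test_default_grids_match_published_search_ranges(self):
        eps = cc.default_epsilon_grid()
        costs = cc.default_cost_grid()
        assert eps[0] == 0.01 and eps[-1] == 1.0 and len(eps) == 100
        assert costs[0] == 30.0 and costs[-1] == 1000.0 and len(costs) == 98
        # the published optima are representable on these grids
        for e in (0.15, 0.36, 0.21):
            assert np.any(np.isclose(eps, e))
        for c in (220.0, 990.0, 120.0):
            assert np.any(np.isclose(costs, c))
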