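import itertools

import numpy as np
import pytest

from ppgbp import models
from ppgbp.models import (
    ConvergenceError,
    MLRModel,
    SingularDesignError,
    SVRModel,
    TrainingSet,
    TreeModel,
    TreeNode,
    fit_mlr,
    fit_svr,
    fit_tree,
    load_model,
    predict,
    save_model,
)


def _random_design(m=50, k=3, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.1, 0.9, size=(m, k))


class TestMLR:
    def test_noiseless_recovery(self):
        X = _random_design()
        y = 100 + 10 * X[:, 0] - 20 * X[:, 1] + 5 * X[:, 2]
        model = fit_mlr(TrainingSet(X, y))
        np.testing.assert_allclose(model.theta, [100, 10, -20, 5], atol=1e-8)

    def test_constant_response(self):
        X = _random_design()
        model = fit_mlr(TrainingSet(X, np.full(len(X), 64.0)))
        np.testing.assert_allclose(model.theta, [64, 0, 0, 0], atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        X = _random_design(seed=7)
        y = 90 + X @ np.array([12.0, -7.0, 3.0]) + rng.normal(0, 2, len(X))
        model = fit_mlr(TrainingSet(X, y))
        design = np.column_stack([np.ones(len(X)), X])
        theta_oracle = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(model.theta, theta_oracle, atol=1e-9)

    def test_residual_mean_zero(self):
        rng = np.random.default_rng(8)
        X = _random_design(seed=8)
        y = 100 + rng.normal(0, 5, len(X))
        model = fit_mlr(TrainingSet(X, y))
        assert abs(np.mean(y - model.predict(X))) < 1e-9

    def test_rank_deficiency_raises(self):
        X = _random_design()
        X[:, 2] = 2 * X[:, 0]  # collinear
        X[:, 1] = X[:, 0]
        with pytest.raises(SingularDesignError):
            fit_mlr(TrainingSet(X, np.arange(len(X), dtype=float)))

    def test_shift_in_y_moves_only_intercept(self):
        rng = np.random.default_rng(9)
        X = _random_design(seed=9)
        y = 100 + X @ np.array([5.0, 1.0, -2.0]) + rng.normal(0, 1, len(X))
        a = fit_mlr(TrainingSet(X, y))
        b = fit_mlr(TrainingSet(X, y + 17.0))
        assert abs(b.theta[0] - a.theta[0] - 17.0) < 1e-8
        np.testing.assert_allclose(a.theta[1:], b.theta[1:], atol=1e-8)


def svr_oracle_1d(x, y, epsilon, C):
    """Exact linear ε-SVR for one feature by enumeration of active sets.

    Each training point is inside the tube (β=0), on the upper/lower tube
    boundary (0<±β<C), or at the box bound (β=±C).  For each assignment the
    KKT equalities form a linear system in (w, b, boundary β); consistent
    solutions are screened against the KKT inequalities and the one with the
    lowest primal objective is returned.
    """
    n = len(x)
    best = None
    for states in itertools.product("iULub", repeat=n):
        boundary = [i for i, s in enumerate(states) if s in "UL"]
        fixed = {i: (C if states[i] == "u" else -C) for i in range(n) if states[i] in "ub"}
        nb = len(boundary)
        # unknowns: w, b, beta_j for boundary points
        A = np.zeros((2 + nb, 2 + nb))
        rhs = np.zeros(2 + nb)
        # stationarity: w - sum beta_i x_i = 0
        A[0, 0] = 1.0
        for j, i in enumerate(boundary):
            A[0, 2 + j] = -x[i]
        rhs[0] = sum(beta * x[i] for i, beta in fixed.items())
        # dual feasibility: sum beta_i = 0
        for j, i in enumerate(boundary):
            A[1, 2 + j] = 1.0
        rhs[1] = -sum(fixed.values())
        # boundary points: y_i - w x_i - b = +/- epsilon
        for j, i in enumerate(boundary):
            A[2 + j, 0] = x[i]
            A[2 + j, 1] = 1.0
            rhs[2 + j] = y[i] - (epsilon if states[i] == "U" else -epsilon)
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            continue
        w, b = sol[0], sol[1]
        betas = dict(fixed)
        ok = True
        for j, i in enumerate(boundary):
            betas[i] = sol[2 + j]
            if states[i] == "U" and not 0 <= betas[i] <= C:
                ok = False
            if states[i] == "L" and not -C <= betas[i] <= 0:
                ok = False
        if not ok:
            continue
        for i in range(n):
            r = y[i] - (w * x[i] + b)
            s = states[i]
            if s == "i" and abs(r) > epsilon + 1e-9:
                ok = False
            elif s == "u" and r < epsilon - 1e-9:
                ok = False
            elif s == "b" and r > -epsilon + 1e-9:
                ok = False
        if not ok:
            continue
        resid = y - (w * x + b)
        primal = 0.5 * w * w + C * np.sum(np.maximum(0.0, np.abs(resid) - epsilon))
        if best is None or primal < best[0] - 1e-12:
            best = (primal, w, b)
    return best


class TestSVR:
    def test_linear_data_matches_active_set_oracle(self):
        # the exact optimum is the flattest line inside the ε-tube, i.e.
        # slope 3 − 2ε/range; over x ∈ [0, 5] that bias is below 0.05
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = 3.0 * x + 2.0
        model = fit_svr(TrainingSet(x[:, None], y), epsilon=0.1, C=1000.0)
        primal, w_star, b_star = svr_oracle_1d(
            (x - x.mean()) / x.std(), y, epsilon=0.1, C=1000.0
        )
        # compare on the original scale
        assert abs(model.weights[0] - w_star / x.std()) < 0.01
        assert abs(model.weights[0] - 3.0) < 0.05
        resid = y - model.predict(x[:, None])
        assert np.all(np.abs(resid) <= 0.1 + 1e-6)

    def test_constant_response(self):
        X = _random_design(m=20, seed=11)
        model = fit_svr(TrainingSet(X, np.full(20, 80.0)), epsilon=1.0)
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-6)
        assert abs(model.bias - 80.0) <= 1.0 + 1e-6

    def test_duplicated_rows_leave_predictions_unchanged(self):
        x = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        y = 3.0 * x + 2.0
        base = fit_svr(TrainingSet(x[:, None], y), epsilon=0.05, C=500.0)
        dup = fit_svr(
            TrainingSet(np.repeat(x, 2)[:, None], np.repeat(y, 2)),
            epsilon=0.05,
            C=500.0,
        )
        grid = np.linspace(0, 2, 7)[:, None]
        np.testing.assert_allclose(base.predict(grid), dup.predict(grid), atol=0.05)

    def test_feasibility_gap_certificate(self):
        rng = np.random.default_rng(12)
        X = _random_design(m=60, seed=12)
        y = 110 + X @ np.array([15.0, -10.0, 5.0]) + rng.normal(0, 2, 60)
        model = fit_svr(TrainingSet(X, y), epsilon=2.0, C=1.0, gap_tol=1e-3)
        assert 0 <= model.gap < model.gap_tol
        assert np.all(np.abs(model.dual_coef) <= model.C + 1e-9)
        # KKT: rows strictly inside the tube carry zero dual coefficient
        # (margin 1e-3 leaves room for the solver's boundary accuracy)
        resid = y - model.predict(X)
        inside = np.abs(resid) < model.epsilon - 1e-3
        assert np.all(np.abs(model.dual_coef[inside]) < 1e-6)

    def test_interpolation_limit(self):
        x = np.linspace(0, 1, 8)
        y = 40.0 * x + 60.0
        model = fit_svr(TrainingSet(x[:, None], y), epsilon=0.0, C=1e4)
        assert np.max(np.abs(y - model.predict(x[:, None]))) < 0.1

    def test_invalid_hyperparameters(self):
        X = _random_design(m=12)
        with pytest.raises(ValueError):
            fit_svr(TrainingSet(X, np.arange(12.0)), epsilon=-1.0)


def brute_force_tree(X, y, max_depth, min_leaf):
    """Exhaustive recursive search over all midpoint splits (oracle)."""

    def best(idx):
        found = None
        for j in range(X.shape[1]):
            values = np.unique(X[idx, j])
            for lo, hi in zip(values[:-1], values[1:]):
                thr = (lo + hi) / 2
                right = idx[X[idx, j] > thr]
                left = idx[X[idx, j] <= thr]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                sse = sum(((y[s] - y[s].mean()) ** 2).sum() for s in (left, right))
                if found is None or sse < found[0] - 1e-12:
                    found = (sse, j, thr)
        return found

    def grow(idx, depth):
        node = {"value": y[idx].mean(), "n": len(idx)}
        if depth >= max_depth or len(idx) < 2 * min_leaf or y[idx].std() == 0:
            return node
        split = best(idx)
        if split is None:
            return node
        _, j, thr = split
        node["feature"], node["threshold"] = j, thr
        node["left"] = grow(idx[X[idx, j] <= thr], depth + 1)
        node["right"] = grow(idx[X[idx, j] > thr], depth + 1)
        return node

    return grow(np.arange(len(y)), 0)


class TestTree:
    def test_constant_response_is_single_leaf(self):
        X = _random_design(m=20, seed=13)
        model = fit_tree(TrainingSet(X, np.full(20, 72.0)), min_leaf=1)
        assert model.root.is_leaf and model.root.value == 72.0

    def test_step_function_learned_exactly(self):
        x = np.linspace(-1, 1, 20)[:, None]
        y = np.where(x[:, 0] < 0, 0.0, 10.0)
        model = fit_tree(TrainingSet(x, y), min_leaf=1)
        assert model.n_leaves == 2
        assert np.all(model.predict(x) == y)

    def test_splits_match_exhaustive_oracle(self):
        rng = np.random.default_rng(14)
        X = rng.uniform(size=(20, 3))
        y = 100 + 30 * X[:, 0] - 20 * X[:, 1] + rng.normal(0, 3, 20)
        model = fit_tree(TrainingSet(X, y), max_depth=2, min_leaf=2)
        oracle = brute_force_tree(X, y, max_depth=2, min_leaf=2)

        def compare(node, ref):
            assert abs(node.value - ref["value"]) < 1e-12
            if node.is_leaf:
                assert "feature" not in ref
                return
            assert node.feature == ref["feature"]
            assert abs(node.threshold - ref["threshold"]) < 1e-12
            compare(node.left, ref["left"])
            compare(node.right, ref["right"])

        compare(model.root, oracle)

    def test_leaf_predictions_are_leaf_means(self):
        rng = np.random.default_rng(15)
        X = rng.uniform(size=(60, 3))
        y = rng.normal(100, 10, 60)
        model = fit_tree(TrainingSet(X, y), max_depth=3, min_leaf=5)

        def check(node, idx):
            if node.is_leaf:
                assert node.n >= 5
                assert abs(node.value - y[idx].mean()) < 1e-10
                return
            right = X[idx, node.feature] > node.threshold
            check(node.left, idx[~right])
            check(node.right, idx[right])

        check(model.root, np.arange(60))

    def test_training_mse_nonincreasing_in_depth(self):
        rng = np.random.default_rng(16)
        X = rng.uniform(size=(80, 3))
        y = 90 + 40 * X[:, 0] + rng.normal(0, 5, 80)
        mses = []
        for depth in (1, 2, 4, 8):
            model = fit_tree(TrainingSet(X, y), max_depth=depth, min_leaf=2)
            mses.append(np.mean((y - model.predict(X)) ** 2))
        assert all(a >= b - 1e-12 for a, b in zip(mses, mses[1:]))


class TestPredictAndPersistence:
    def test_mlr_arithmetic(self):
        model = MLRModel(theta=np.array([100.0, 10, -20, 5]), residual_sd=0.0, n_features=3)
        assert predict(model, [[0.5, 0.2, 0.7]])[0] == pytest.approx(104.5)

    def test_single_leaf_tree(self):
        tree = TreeModel(TreeNode(value=60.0, n=1), 1, 1, 0.0, n_features=3)
        assert predict(tree, [[0.1, 0.9, 0.4]])[0] == 60.0

    def test_svr_linear_form(self):
        model = SVRModel(
            weights=np.array([3.0]), bias=2.0, epsilon=0.1, C=1.0,
            dual_coef=np.empty(0), primal_objective=0.0, dual_objective=0.0,
            gap=0.0, gap_tol=1e-3, feature_mean=np.zeros(1),
            feature_scale=np.ones(1), n_features=1,
        )
        assert predict(model, [[4.0]])[0] == pytest.approx(14.0)

    def test_schema_mismatch(self):
        model = MLRModel(theta=np.array([1.0, 2.0]), residual_sd=0.0, n_features=1)
        with pytest.raises(ValueError):
            predict(model, [[1.0, 2.0]])

    @pytest.mark.parametrize("kind", ["mlr", "svr", "tree"])
    def test_save_load_round_trip(self, kind, tmp_path):
        rng = np.random.default_rng(17)
        X = rng.uniform(size=(30, 3))
        y = 100 + 20 * X[:, 0] + rng.normal(0, 2, 30)
        train = TrainingSet(X, y)
        model = {"mlr": fit_mlr, "tree": fit_tree}.get(kind, lambda t: fit_svr(t))(train)
        save_model(model, tmp_path / "m.txt")
        back = load_model(tmp_path / "m.txt")
        np.testing.assert_allclose(predict(model, X), predict(back, X), atol=1e-12)
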