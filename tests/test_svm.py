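"""SVM dual solutions against a brute-force QP oracle and KKT contracts."""

import numpy as np
import pytest
from scipy.optimize import minimize

from mciprog import KernelSpec, svm_decision, svm_fit
from mciprog.svm import _kernel_matrix, svm_fit_precomputed


def qp_oracle(X, y, kernel, C):
    """Solve the boxed dual max directly with SLSQP on the Gram matrix."""
    K = _kernel_matrix(kernel, X, X)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K

    def neg_dual(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def jac(a):
        return -(np.ones(n) - Q @ a)

    res = minimize(
        neg_dual,
        np.zeros(n),
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    alpha = res.x
    # intercept from KKT: equalities at free SVs; otherwise the feasible
    # interval from the bound constraints, taken at its midpoint
    f = K @ (alpha * y)  # decision values without intercept
    e = y - f
    free = (alpha > 1e-6 * C) & (alpha < C * (1 - 1e-6))
    if free.any():
        b = float(np.mean(e[free]))
    else:
        lower, upper = [], []
        for i in range(n):
            if alpha[i] <= 1e-6 * C:  # y_i (f_i + b) >= 1
                (lower if y[i] == 1 else upper).append(e[i])
            else:  # alpha at C: y_i (f_i + b) <= 1
                (upper if y[i] == 1 else lower).append(e[i])
        b = float((max(lower) + min(upper)) / 2)
    return alpha, b


def oracle_decisions(X_train, y, alpha, b, kernel, X_new):
    K = _kernel_matrix(kernel, X_new, X_train)
    return K @ (alpha * y) + b


def toy_points(seed, n=12):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = np.where(X[:, 0] + 0.5 * X[:, 1] + 0.1 * rng.normal(size=n) > 0, 1, -1)
    if len(np.unique(y)) < 2:
        y[0] = -y[0]
    return X, y


class TestHardMargin:
    def test_one_dimensional_symmetric_solution(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        model = svm_fit(X, y, "linear", C=1e6, tol=1e-8)
        assert model.W[0] == pytest.approx(1.0, abs=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-6)
        assert set(model.support_) == {0, 1}
        np.testing.assert_allclose(svm_decision(model, X), [-1.0, 1.0], atol=1e-6)


class TestDualFeasibility:
    @pytest.mark.parametrize("kernel", [KernelSpec("linear"), KernelSpec("rbf", sigma=1.5)])
    @pytest.mark.parametrize("C", [0.5, 10.0])
    def test_kkt_constraints_hold(self, kernel, C):
        X, y = toy_points(3, n=15)
        model = svm_fit(X, y, kernel, C=C, tol=1e-8)
        assert abs(np.dot(model.alpha, model.y_train)) < 1e-8
        assert np.all(model.alpha >= -1e-12)
        assert np.all(model.alpha <= C + 1e-8)

    def test_free_support_vectors_sit_on_margin(self):
        X, y = toy_points(5, n=15)
        model = svm_fit(X, y, "linear", C=1.0, tol=1e-8)
        d = svm_decision(model, X)
        free = (model.alpha > 1e-6) & (model.alpha < 1.0 - 1e-6)
        if free.any():
            np.testing.assert_allclose(np.abs(d[free]) * 1.0, 1.0, atol=1e-4)
            np.testing.assert_allclose(d[free], y[free], atol=1e-4)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize(
        "kernel", [KernelSpec("linear"), KernelSpec("rbf", sigma=2.0)]
    )
    def test_decision_values_match_bruteforce_qp(self, seed, kernel):
        X, y = toy_points(seed)
        C = 5.0
        model = svm_fit(X, y, kernel, C=C, tol=1e-10)
        alpha, b = qp_oracle(X, y, kernel, C)
        X_new = np.random.default_rng(seed + 100).normal(size=(5, 2))
        ours = svm_decision(model, X_new)
        theirs = oracle_decisions(X, y, alpha, b, kernel, X_new)
        np.testing.assert_allclose(ours, theirs, atol=1e-5)


class TestDecision:
    def test_representer_identity_linear(self):
        X, y = toy_points(7)
        model = svm_fit(X, y, "linear", C=2.0, tol=1e-8)
        X_new = np.random.default_rng(0).normal(size=(6, 2))
        np.testing.assert_allclose(
            svm_decision(model, X_new), X_new @ model.W + model.b, atol=1e-10
        )

    def test_permutation_equivariance(self):
        X, y = toy_points(11, n=14)
        perm = [1, 0]
        m1 = svm_fit(X, y, "linear", C=1.0, tol=1e-8)
        m2 = svm_fit(X[:, perm], y, "linear", C=1.0, tol=1e-8)
        np.testing.assert_allclose(m1.W[perm], m2.W, atol=1e-8)
        X_new = np.random.default_rng(1).normal(size=(4, 2))
        np.testing.assert_allclose(
            svm_decision(m1, X_new), svm_decision(m2, X_new[:, perm]), atol=1e-8
        )

    def test_dimension_mismatch_rejected(self):
        X, y = toy_points(2)
        model = svm_fit(X, y, "linear", C=1.0)
        with pytest.raises(ValueError, match="feature count"):
            svm_decision(model, np.zeros((3, 5)))

    def test_precomputed_kernel_path(self):
        X, y = toy_points(4)
        K = X @ X.T
        model = svm_fit_precomputed(K, y, C=1.0, tol=1e-8)
        ref = svm_fit(X, y, "linear", C=1.0, tol=1e-8)
        np.testing.assert_allclose(
            svm_decision(model, X @ X.T), svm_decision(ref, X), atol=1e-5
        )

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            svm_fit(np.ones((4, 2)), np.ones(4, int), "linear")

    def test_invalid_C_rejected(self):
        X, y = toy_points(0)
        with pytest.raises(ValueError, match="C"):
            svm_fit(X, y, "linear", C=0.0)


class TestBoxConstraintMonotonicity:
    def test_larger_C_never_increases_margin_violations(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 0] + rng.normal(scale=1.0, size=30) > 0, 1, -1)
        violations = []
        for C in (0.1, 0.2, 0.4, 0.8):
            model = svm_fit(X, y, "linear", C=C, tol=1e-8)
            d = svm_decision(model, X)
            violations.append(int(np.sum(y * d < 1 - 1e-8)))
        assert all(a >= b for a, b in zip(violations, violations[1:]))
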