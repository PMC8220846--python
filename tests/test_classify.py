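"""SMO-trained SVMs and the small feed-forward network."""

import numpy as np
import pytest
from scipy import optimize

from gaitpress.classify import (
    KernelSpec,
    NNModel,
    SVMModel,
    decision_values,
    default_gamma,
    kernel_matrix,
    predict_nn,
    predict_svm,
    train_nn,
    train_svm,
)


def brute_force_dual(K, y, C):
    """Solve the soft-margin dual QP directly (SLSQP active-set oracle)."""
    n = K.shape[0]
    Q = (y[:, None] * y[None, :]) * K

    res = optimize.minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.full(n, C / 2),
        jac=lambda a: Q @ a - np.ones(n),
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"ftol": 1e-12, "maxiter": 500},
    )
    assert res.success
    alpha = res.x
    # bias from a free support vector (or margin average)
    f_no_b = (alpha * y) @ K
    free = (alpha > 1e-6) & (alpha < C - 1e-6)
    idx = np.flatnonzero(free if free.any() else alpha > 1e-6)
    b = float(np.mean(y[idx] - f_no_b[idx]))
    return alpha, b


class TestSVMBinary:
    def test_two_point_margin_problem(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["A", "B"])
        model = train_svm(X, y, KernelSpec("linear"), C=1.0)
        f = decision_values(model, X)
        assert f[0] == pytest.approx(-1.0, abs=1e-6)
        assert f[1] == pytest.approx(1.0, abs=1e-6)
        assert decision_values(model, [[0.0]])[0] == pytest.approx(0.0, abs=1e-6)

    def test_xor_rbf_separates(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array(["even", "even", "odd", "odd"])
        model = train_svm(X, y, KernelSpec("rbf", gamma=1.0), C=1.0)
        assert np.all(predict_svm(model, X).labels == y)

    def test_decision_matches_brute_force_qp(self, rng):
        # <= 6 training points, compare decision values against the QP oracle
        for kernel in (KernelSpec("linear"), KernelSpec("rbf", gamma=0.7)):
            X = rng.normal(0, 1, (6, 2))
            y_str = np.array(["A", "A", "A", "B", "B", "B"])
            y = np.where(y_str == "B", 1.0, -1.0)
            model = train_svm(X, y_str, kernel, C=1.0, tol=1e-5)
            K = kernel_matrix(X, X, kernel, kernel.gamma)
            alpha, b = brute_force_dual(K, y, 1.0)
            oracle = K @ (alpha * y) + b
            ours = decision_values(model, X)
            assert np.max(np.abs(ours - oracle)) < 1e-4

    def test_dual_feasibility_and_kkt(self, rng):
        X = np.vstack([rng.normal(-1, 1, (30, 3)), rng.normal(1, 1, (30, 3))])
        y_str = np.repeat(["A", "B"], 30)
        model = train_svm(X, y_str, KernelSpec("linear"), C=1.0, tol=1e-4)
        bin_ = model.binaries[(0, 1)]
        alpha = np.abs(bin_.dual_coef)
        assert np.all(alpha >= -1e-12) and np.all(alpha <= 1.0 + 1e-12)
        assert abs(bin_.dual_coef.sum()) < 1e-8  # sum alpha_i y_i = 0
        # free support vectors sit on the margin: |f| = 1 within tolerance
        f_sv = decision_values(model, bin_.support_vectors)
        free = (alpha > 1e-6) & (alpha < 1.0 - 1e-6)
        if free.any():
            y_sv = np.sign(bin_.dual_coef[free])
            assert np.max(np.abs(f_sv[free] - y_sv)) < 5e-2

    def test_objective_monotone_nondecreasing(self, rng):
        X = rng.normal(0, 1, (40, 2))
        y = np.where(X[:, 0] + 0.3 * rng.normal(0, 1, 40) > 0, "B", "A")
        if len(set(y)) < 2:
            pytest.skip("degenerate draw")
        model = train_svm(X, y, KernelSpec("rbf", gamma=0.5), C=1.0,
                          record_objective=True)
        hist = model.binaries[(0, 1)].objective_history
        assert len(hist) > 1
        assert np.all(np.diff(hist) >= -1e-10)


class TestSVMMulticlass:
    def test_one_vs_one_voting_and_permutation_equivariance(self, rng):
        X = np.vstack([rng.normal(m, 0.4, (20, 2)) for m in ([0, 0], [3, 0], [0, 3])])
        y = np.repeat(["a", "b", "c"], 20)
        model = train_svm(X, y, KernelSpec("linear"))
        pred = predict_svm(model, X).labels
        assert (pred == y).mean() == 1.0
        # renaming classes permutes predictions accordingly
        rename = {"a": "z", "b": "x", "c": "y"}
        y2 = np.array([rename[c] for c in y])
        model2 = train_svm(X, y2, KernelSpec("linear"))
        pred2 = predict_svm(model2, X).labels
        assert np.all(pred2 == np.array([rename[c] for c in pred]))

    def test_duplicated_test_row_invariance(self, rng):
        X = np.vstack([rng.normal(-2, 0.5, (10, 2)), rng.normal(2, 0.5, (10, 2))])
        y = np.repeat(["a", "b"], 10)
        model = train_svm(X, y, KernelSpec("linear"))
        single = predict_svm(model, X[:3]).labels
        doubled = predict_svm(model, np.vstack([X[:3], X[2:3]])).labels
        assert np.all(doubled[:3] == single)
        assert doubled[3] == single[2]

    def test_kernel_sum_oracle(self, rng):
        X = np.vstack([rng.normal(-1, 1, (15, 3)), rng.normal(1, 1, (15, 3))])
        y = np.repeat(["a", "b"], 15)
        spec = KernelSpec("rbf", gamma=0.3)
        model = train_svm(X, y, spec, C=1.0)
        bin_ = model.binaries[(0, 1)]
        Xt = rng.normal(0, 1, (10, 3))
        ours = decision_values(model, Xt)
        manual = np.array(
            [
                sum(
                    coef * np.exp(-0.3 * np.sum((sv - x) ** 2))
                    for sv, coef in zip(bin_.support_vectors, bin_.dual_coef)
                )
                + bin_.bias
                for x in Xt
            ]
        )
        assert np.max(np.abs(ours - manual)) <= 1e-10

    def test_agreement_with_sklearn(self, rng):
        from sklearn.svm import SVC

        X = np.vstack([rng.normal(m, 0.6, (25, 3)) for m in ([0, 0, 0], [3, 0, 0],
                                                             [0, 3, 0], [0, 0, 3])])
        y = np.repeat(["n", "i", "o", "f"], 25)
        ours = predict_svm(train_svm(X, y, KernelSpec("rbf")), X).labels
        theirs = SVC(C=1.0, kernel="rbf", gamma="scale").fit(X, y).predict(X)
        assert (ours == theirs).mean() > 0.97

    def test_default_gamma_is_scale_convention(self, rng):
        X = rng.normal(0, 2, (30, 5))
        assert default_gamma(X) == pytest.approx(1.0 / (5 * X.var()))
        model = train_svm(np.vstack([X, X + 5]), np.repeat(["a", "b"], 30),
                          KernelSpec("rbf"), C=1.0)
        full = np.vstack([X, X + 5])
        assert model.gamma == pytest.approx(1.0 / (5 * full.var()))

    def test_invalid_inputs_rejected(self, rng):
        X = rng.normal(0, 1, (10, 2))
        with pytest.raises(ValueError):
            train_svm(X, np.repeat(["a"], 10))  # single class
        Xbad = X.copy()
        Xbad[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_svm(Xbad, np.repeat(["a", "b"], 5))
        model = train_svm(X, np.repeat(["a", "b"], 5))
        with pytest.raises(ValueError):
            predict_svm(model, np.zeros((2, 9)))

    def test_json_round_trip(self, rng):
        X = np.vstack([rng.normal(-1, 0.5, (10, 2)), rng.normal(1, 0.5, (10, 2))])
        y = np.repeat(["a", "b"], 10)
        model = train_svm(X, y, KernelSpec("rbf"))
        back = SVMModel.from_json(model.to_json())
        assert np.all(predict_svm(back, X).labels == predict_svm(model, X).labels)


class TestNN:
    def blobs(self, rng):
        X = np.vstack([rng.normal(-2, 0.5, (40, 2)), rng.normal(2, 0.5, (40, 2))])
        return X, np.repeat(["a", "b"], 40)

    def test_separable_blobs_learned_with_defaults(self, rng):
        X, y = self.blobs(rng)
        model = train_nn(X, y, seed=1)
        assert model.w1.shape[1] == 10  # default hidden width
        assert (predict_nn(model, X).labels == y).mean() == 1.0

    def test_same_seed_identical_weights(self, rng):
        X, y = self.blobs(rng)
        a = train_nn(X, y, seed=7)
        b = train_nn(X, y, seed=7)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)
        c = train_nn(X, y, seed=8)
        assert not np.array_equal(a.w1, c.w1)

    def test_softmax_rows_sum_to_one(self, rng):
        X, y = self.blobs(rng)
        model = train_nn(X, y, epochs=5, seed=0)
        scores = predict_nn(model, rng.normal(0, 1, (7, 2))).scores
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-12)

    def test_forward_pass_matches_matrix_recurrence_oracle(self, rng):
        X, y = self.blobs(rng)
        model = train_nn(X, y, epochs=3, seed=2)
        Xt = rng.normal(0, 1, (5, 2))
        h = 1 / (1 + np.exp(-(Xt @ model.w1 + model.b1)))
        z = h @ model.w2 + model.b2
        e = np.exp(z - z.max(axis=1, keepdims=True))
        prob = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(predict_nn(model, Xt).scores, prob, atol=1e-12)

    def test_zero_weights_tie_resolved_by_class_order(self):
        model = NNModel(np.zeros((2, 10)), np.zeros(10), np.zeros((10, 3)),
                        np.zeros(3), ("first", "second", "third"))
        pred = predict_nn(model, np.array([[1.0, 2.0]]))
        assert np.allclose(pred.scores, 1 / 3)
        assert pred.labels[0] == "first"

    def test_dimension_mismatch_rejected(self, rng):
        X, y = self.blobs(rng)
        model = train_nn(X, y, epochs=2, seed=0)
        with pytest.raises(ValueError):
            predict_nn(model, np.zeros((3, 5)))

    def test_epochs_validated(self, rng):
        X, y = self.blobs(rng)
        with pytest.raises(ValueError):
            train_nn(X, y, epochs=0)
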