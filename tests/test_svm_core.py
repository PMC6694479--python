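"""Soft-margin SVM dual: analytic solutions, QP-oracle equivalence, CV."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from multikernel import (
    KernelSpec,
    compute_gram,
    cross_validate_svm,
    no_information_rate,
    solve_svm_dual,
    svm_predict,
)
from multikernel.kernels import GramMatrix
from multikernel.svm_core import SVMError, dual_objective, encode_labels

from conftest import make_gaussian_toy


def qp_oracle(K, y, C):
    """Dense QP solve of the SVM dual via SLSQP — independent of libsvm."""
    n = y.size
    Q = (y[:, None] * K) * y[None, :]

    def neg_dual(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def grad(a):
        return -(np.ones(n) - Q @ a)

    res = minimize(
        neg_dual,
        np.full(n, min(C, 1.0) / 2),
        jac=grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    return -res.fun, res.x


def test_two_point_analytic_solution(separable_1d):
    """x = -1, +1 with opposite labels: alpha = (1/2, 1/2), b = 0, f(x) = x."""
    X, y = separable_1d
    g = compute_gram(X, X, KernelSpec("linear"))
    sol = solve_svm_dual(g, y, C=10.0)
    np.testing.assert_allclose(sol.alpha, [0.5, 0.5], atol=1e-6)
    assert sol.bias == pytest.approx(0.0, abs=1e-6)
    new = pd.DataFrame({"x": [2.0, 0.0]}, index=["p", "q"])
    f, labels = svm_predict(sol, compute_gram(new, X, KernelSpec("linear")))
    np.testing.assert_allclose(f, [2.0, 0.0], atol=1e-6)
    assert labels[0] == 1.0
    assert labels[1] == 1.0  # tie at f = 0 maps to +1


def test_single_class_labels_rejected(separable_1d):
    X, _ = separable_1d
    g = compute_gram(X, X, KernelSpec("linear"))
    with pytest.raises(SVMError, match="two classes"):
        solve_svm_dual(g, np.ones(2), C=1.0)


@pytest.mark.parametrize("seed", range(20))
def test_dual_objective_matches_qp_oracle(seed):
    """Attained dual value agrees with a dense SLSQP solve within 1e-6."""
    r = np.random.default_rng(seed)
    n = int(r.integers(10, 21))
    X = pd.DataFrame(r.normal(size=(n, 3)), index=[f"s{i}" for i in range(n)])
    y = np.where(r.random(n) < 0.5, -1.0, 1.0)
    if np.unique(y).size < 2:
        y[0] = -y[0]
    spec = KernelSpec("radial", sigma=float(r.uniform(0.2, 2.0)))
    g = compute_gram(X, X, spec)
    C = float(r.choice([0.1, 1.0, 10.0]))
    sol = solve_svm_dual(g, y, C)
    oracle_obj, _ = qp_oracle(g.values, y, C)
    assert sol.objective == pytest.approx(oracle_obj, abs=1e-6, rel=1e-6)
    # KKT basics
    assert np.all(sol.alpha >= -1e-8) and np.all(sol.alpha <= C + 1e-8)
    assert abs(sol.alpha @ sol.y) <= 1e-6


def test_xor_objective_matches_oracle():
    X = pd.DataFrame([[0.0, 0], [0, 1], [1, 0], [1, 1]],
                     index=list("abcd"), columns=["f1", "f2"])
    y = np.array([-1.0, 1.0, 1.0, -1.0])
    g = compute_gram(X, X, KernelSpec("linear"))
    sol = solve_svm_dual(g, y, C=1.0)
    oracle_obj, _ = qp_oracle(g.values, y, 1.0)
    assert sol.objective == pytest.approx(oracle_obj, abs=1e-6)


def test_training_error_non_increasing_in_C():
    X, y = make_gaussian_toy(3, n_per_class=15, gap=6.0)
    g = compute_gram(X, X, KernelSpec("linear"))
    errors = []
    for C in (0.001, 0.01, 0.1, 1.0, 10.0):
        sol = solve_svm_dual(g, y, C)
        _, pred = svm_predict(sol, g)
        errors.append(float(np.mean(pred != y)))
    assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errors, errors[1:]))


def test_gram_scaling_with_compensated_C_keeps_predictions():
    X, y = make_gaussian_toy(4, n_per_class=10, gap=3.0)
    spec = KernelSpec("linear")
    g = compute_gram(X, X, spec)
    c = 5.0
    scaled = GramMatrix(c * g.values, g.row_ids, g.col_ids, spec)
    sol = solve_svm_dual(g, y, C=1.0)
    sol_scaled = solve_svm_dual(scaled, y, C=1.0 / c)
    _, p1 = svm_predict(sol, g)
    _, p2 = svm_predict(sol_scaled, scaled)
    np.testing.assert_array_equal(p1, p2)


def test_margin_property_on_training_points(gaussian_toy):
    X, y = gaussian_toy
    g = compute_gram(X, X, KernelSpec("radial", sigma=0.5))
    sol = solve_svm_dual(g, y, C=10.0)
    _, pred = svm_predict(sol, g)
    assert np.mean(pred == y) == 1.0


def test_predict_id_mismatch_rejected(separable_1d):
    X, y = separable_1d
    g = compute_gram(X, X, KernelSpec("linear"))
    sol = solve_svm_dual(g, y, C=1.0)
    bad = GramMatrix(np.ones((1, 2)), ["new"], ["neg", "OTHER"])
    with pytest.raises(SVMError):
        svm_predict(sol, bad)


def test_label_encoding_is_lexicographic():
    enc, mapping = encode_labels(np.array(["tumor", "normal", "tumor"]))
    assert mapping == {"normal": -1, "tumor": 1}
    np.testing.assert_array_equal(enc, [1.0, -1.0, 1.0])


@pytest.mark.parametrize(
    "labels, expected",
    [([1] * 7 + [-1] * 3, 0.7), ([1, -1, 1, -1], 0.5), ([42], 1.0)],
)
def test_no_information_rate(labels, expected):
    assert no_information_rate(labels) == pytest.approx(expected)


def test_no_information_rate_empty():
    with pytest.raises(SVMError):
        no_information_rate([])


class TestCrossValidation:
    def test_separable_toy_reaches_perfect_accuracy(self):
        X, y = make_gaussian_toy(7, n_per_class=30, gap=6.0)
        specs = [KernelSpec("radial", sigma=s) for s in (0.01, 0.1, 1.0)]
        cv = cross_validate_svm(X, y, specs, C_grid=(1.0, 10.0), k=5, seed=0)
        assert cv.best_acc == pytest.approx(1.0)
        assert set(cv.table.columns) >= {"spec_label", "C", "mean_acc", "sd_acc"}
        assert (cv.table["mean_acc"] <= 1.0).all() and (cv.table["mean_acc"] >= 0.0).all()

    def test_same_seed_reproduces_result(self):
        X, y = make_gaussian_toy(8, n_per_class=15, gap=2.0)
        specs = [KernelSpec("linear")]
        cv1 = cross_validate_svm(X, y, specs, C_grid=(1.0,), k=5, seed=3)
        cv2 = cross_validate_svm(X, y, specs, C_grid=(1.0,), k=5, seed=3)
        pd.testing.assert_frame_equal(cv1.table, cv2.table)
        np.testing.assert_array_equal(cv1.fold_assignments, cv2.fold_assignments)

    def test_folds_partition_and_stratify(self):
        X, y = make_gaussian_toy(9, n_per_class=25, gap=2.0)
        cv = cross_validate_svm(X, y, [KernelSpec("linear")], C_grid=(1.0,), k=5, seed=1)
        assert sorted(np.unique(cv.fold_assignments)) == list(range(5))
        for f in range(5):
            fold_y = y[cv.fold_assignments == f]
            assert abs(np.mean(fold_y > 0) - 0.5) <= 0.1

    def test_shuffled_labels_score_near_chance(self):
        accs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X, y = make_gaussian_toy(seed, n_per_class=20, gap=4.0)
            y_perm = r.permutation(y)
            cv = cross_validate_svm(X, y_perm, [KernelSpec("linear")],
                                    C_grid=(1.0,), k=5, seed=seed)
            accs.append(cv.best_acc)
        # permuted labels: accuracy should hover around NIR = 0.5
        assert abs(np.mean(accs) - 0.5) < 3 * np.std(accs, ddof=1) + 1e-9

    def test_too_small_input_rejected(self):
        X, y = make_gaussian_toy(1, n_per_class=4)
        with pytest.raises(SVMError):
            cross_validate_svm(X, y, [KernelSpec("linear")], k=10, seed=0)
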