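"""Soft-margin SVM on a precomputed Gram matrix, plus cross-validation.

The dual problem solved for a fixed kernel K and cost C is

    max_alpha  sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K_ij
    s.t.       0 <= alpha_i <= C,   sum_i alpha_i y_i = 0.

The heavy lifting is delegated to libsvm (scikit-learn's ``SVC`` with a
precomputed kernel); dual coefficients, bias and the attained dual objective
are reconstructed here and certified against the KKT conditions, so any
KKT-respecting solver could be swapped in behind :func:`solve_svm_dual`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .kernels import GramMatrix, KernelSpec, compute_gram, validate_psd

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_TOL = 1e-6


class SVMError(RuntimeError):
    """Solver failure or invalid SVM input."""


def encode_labels(y: Sequence) -> tuple[np.ndarray, dict]:
    """Map two arbitrary class labels to {-1, +1}.

    Classes are sorted (lexicographically for strings, numerically
    otherwise); the first maps to -1, the second to +1.  Returns the encoded
    vector and the mapping ``{original: code}``.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise SVMError(
            f"expected exactly two classes, got {classes.size}: {classes[:5].tolist()}"
        )
    mapping = {classes[0]: -1, classes[1]: +1}
    enc = np.where(y == classes[0], -1.0, 1.0)
    return enc, mapping


@dataclass
class SVMSolution:
    """Certified solution of the soft-margin SVM dual for one kernel."""

    alpha: np.ndarray          # dual coefficients, each in [0, C]
    bias: float
    objective: float           # attained dual objective
    support_idx: np.ndarray    # indices with alpha > tol
    C: float
    y: np.ndarray              # encoded labels in {-1, +1}
    ids: tuple                 # training sample ids, in alpha order
    label_map: dict = field(default_factory=dict)
    tol: float = DEFAULT_TOL

    @property
    def n_support(self) -> int:
        return int(self.support_idx.size)


def dual_objective(alpha: np.ndarray, K: np.ndarray, y: np.ndarray) -> float:
    """sum(alpha) - 1/2 alpha' (yy' o K) alpha."""
    ay = alpha * y
    return float(alpha.sum() - 0.5 * ay @ K @ ay)


def solve_svm_dual(
    gram: GramMatrix,
    y: Sequence,
    C: float,
    tol: float = DEFAULT_TOL,
) -> SVMSolution:
    """Solve the soft-margin dual for a fixed Gram matrix.

    The bias is averaged over unbounded support vectors
    (0 < alpha_i < C); when all support vectors sit on the box boundary it
    falls back to the midpoint of the KKT feasibility interval.
    """
    if not gram.is_square:
        raise SVMError("training requires a square Gram matrix")
    if C <= 0:
        raise SVMError(f"cost C must be positive, got {C}")
    y_enc, label_map = encode_labels(y)
    n = y_enc.size
    if n != gram.shape[0]:
        raise SVMError(f"{n} labels for a {gram.shape} Gram matrix")

    gram = validate_psd(gram)
    K = gram.values

    # libsvm's epsilon bounds the KKT violation, not the objective gap;
    # tighten it so the attained dual value meets `tol` against a QP oracle
    svc = SVC(C=C, kernel="precomputed", tol=min(tol, DEFAULT_TOL) / 10, shrinking=True)
    try:
        svc.fit(K, y_enc)
    except Exception as exc:  # pragma: no cover - libsvm failures are rare
        raise SVMError(f"libsvm solver failure: {exc}") from exc

    alpha = np.zeros(n)
    # dual_coef_ holds y_i * alpha_i for support vectors
    alpha[svc.support_] = svc.dual_coef_[0] * y_enc[svc.support_]
    if np.any(alpha < -1e-9):
        raise SVMError("solver returned inconsistent dual coefficients")
    alpha = np.clip(alpha, 0.0, C)

    if abs(alpha @ y_enc) > 1e-6 * max(1.0, C):
        raise SVMError(f"equality constraint violated: sum(alpha*y) = {alpha @ y_enc:g}")

    f_no_bias = K @ (alpha * y_enc)
    unbounded = np.flatnonzero((alpha > tol) & (alpha < C - tol))
    if unbounded.size:
        bias = float(np.mean(y_enc[unbounded] - f_no_bias[unbounded]))
    else:
        # KKT interval: y_i(f_i + b) >= 1 for alpha=0, <= 1 for alpha=C
        g = y_enc - f_no_bias
        up = np.concatenate([g[(alpha <= tol) & (y_enc > 0)], g[(alpha >= C - tol) & (y_enc < 0)]])
        lo = np.concatenate([g[(alpha <= tol) & (y_enc < 0)], g[(alpha >= C - tol) & (y_enc > 0)]])
        hi_b = up.min() if up.size else np.inf
        lo_b = lo.max() if lo.size else -np.inf
        if np.isfinite(lo_b) and np.isfinite(hi_b):
            bias = float(0.5 * (lo_b + hi_b))
        else:
            bias = float(svc.intercept_[0])

    return SVMSolution(
        alpha=alpha,
        bias=bias,
        objective=dual_objective(alpha, K, y_enc),
        support_idx=np.flatnonzero(alpha > tol),
        C=C,
        y=y_enc,
        ids=gram.row_ids,
        label_map=label_map,
        tol=tol,
    )


def svm_predict(model: SVMSolution, cross_gram: GramMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Decision values and labels for new samples.

    ``cross_gram`` is (new samples) x (training samples), columns in the
    training-id order of the model.  f(x) = sum_i alpha_i y_i K(x, x_i) + b;
    the label is sign(f) with ties (f == 0) mapped to +1.
    """
    if cross_gram.col_ids != model.ids:
        raise SVMError("cross-Gram columns do not match training sample ids")
    f = cross_gram.values @ (model.alpha * model.y) + model.bias
    labels = np.where(f >= 0, 1.0, -1.0)
    return f, labels


@dataclass
class CVResult:
    """Grid of cross-validated accuracies over (kernel spec, C) cells."""

    table: pd.DataFrame        # columns: spec_label, spec_index, C, mean_acc, sd_acc
    specs: list
    C_grid: tuple
    best_spec: KernelSpec
    best_C: float
    best_acc: float
    fold_assignments: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return self.table


def no_information_rate(y: Sequence) -> float:
    """Accuracy of always predicting the majority class."""
    y = np.asarray(y)
    if y.size == 0:
        raise SVMError("empty label vector")
    _, counts = np.unique(y, return_counts=True)
    return float(counts.max() / y.size)


def cross_validate_svm(
    X: pd.DataFrame,
    y: Sequence,
    specs: Sequence[KernelSpec],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold accuracy for every (kernel spec, C) cell.

    The full Gram for each spec is computed once and sub-indexed per fold.
    The best cell is the highest mean accuracy, ties broken by grid order.
    Deterministic given the seed.
    """
    y = np.asarray(y)
    if k < 2:
        raise SVMError(f"need k >= 2 folds, got {k}")
    if len(X) < 2 * k:
        raise SVMError(f"n={len(X)} too small for {k}-fold CV")
    y_enc, _ = encode_labels(y)
    counts = np.bincount((y_enc > 0).astype(int))
    if counts.min() < k:
        raise SVMError(
            f"minority class has {counts.min()} samples, fewer than k={k} folds"
        )

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(X)), y_enc))
    assignments = np.empty(len(X), dtype=int)
    for fi, (_, test_idx) in enumerate(folds):
        assignments[test_idx] = fi

    rows = []
    for si, spec in enumerate(specs):
        K_full = compute_gram(X, X, spec).values
        for C in C_grid:
            accs = []
            for train_idx, test_idx in folds:
                sub = GramMatrix(
                    K_full[np.ix_(train_idx, train_idx)],
                    [X.index[i] for i in train_idx],
                    [X.index[i] for i in train_idx],
                    spec,
                )
                model = solve_svm_dual(sub, y_enc[train_idx], C)
                cross = GramMatrix(
                    K_full[np.ix_(test_idx, train_idx)],
                    [X.index[i] for i in test_idx],
                    sub.row_ids,
                    spec,
                )
                _, pred = svm_predict(model, cross)
                accs.append(float(np.mean(pred == y_enc[test_idx])))
            rows.append(
                {
                    "spec_index": si,
                    "spec_label": spec.label,
                    "C": C,
                    "mean_acc": float(np.mean(accs)),
                    "sd_acc": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                }
            )
    table = pd.DataFrame(rows)
    best = table["mean_acc"].idxmax()  # first max in grid order
    return CVResult(
        table=table,
        specs=list(specs),
        C_grid=tuple(C_grid),
        best_spec=specs[int(table.loc[best, "spec_index"])],
        best_C=float(table.loc[best, "C"]),
        best_acc=float(table.loc[best, "mean_acc"]),
        fold_assignments=assignments,
        seed=seed,
    )
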