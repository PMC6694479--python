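"""Wrapper-method multiple kernel learning: SEMKL and SimpleMKL.

Both methods learn simplex weights eta (eta_m >= 0, sum eta_m = 1) over M
candidate Gram matrices by alternating a full SVM solve on the combined
kernel K(eta) = sum_m eta_m K_m with a weight update:

* SEMKL updates eta in closed form, eta_m <- ||f_m|| / sum_k ||f_k|| with
  ||f_m||^2 = eta_m^2 alpha' (yy' o K_m) alpha — the update that follows
  from the Cauchy-Schwarz inequality, so no line search is needed.
* SimpleMKL performs reduced-gradient descent on the simplex: the gradient
  of the optimal-value function J(eta) is g_m = -1/2 alpha'(yy' o K_m)alpha
  (Danskin), the largest-weight component serves as pivot, descent
  directions that would drive a zero weight negative are clipped, and a
  line search (golden section with an Armijo fallback) picks the step —
  every candidate step re-solves the SVM.

Both minimize the same convex objective J(eta), so on small problems their
final objectives agree; they differ in cost per iteration and trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kernels import GramMatrix, KernelSpec, combine_grams
from .svm_core import SVMSolution, solve_svm_dual, svm_predict, SVMError

#: weights below this are considered numerically dead, zeroed and renormalized
WEIGHT_FLOOR = 1e-8


class MKLError(RuntimeError):
    """MKL solver failure or invalid input."""


@dataclass
class MKLModel:
    """Learned kernel combination + embedded SVM solution."""

    weights: np.ndarray            # eta on the simplex
    svm: SVMSolution               # solution for the combined kernel
    specs: list                    # KernelSpec per kernel (may be None)
    trace: list = field(default_factory=list)   # per-iteration dicts
    converged: bool = False
    method: str = ""
    C: float = 1.0

    @property
    def objective(self) -> float:
        return self.svm.objective

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "C": self.C,
            "weights": [round(float(w), 10) for w in self.weights],
            "alpha": self.svm.alpha.tolist(),
            "bias": float(self.svm.bias),
            "objective": float(self.svm.objective),
            "converged": bool(self.converged),
            "n_iter": len(self.trace),
            "specs": [s.to_dict() if isinstance(s, KernelSpec) else str(s) for s in self.specs],
        }


def _check_grams(grams: Sequence[GramMatrix]) -> list[GramMatrix]:
    grams = list(grams)
    if not grams:
        raise MKLError("need at least one Gram matrix")
    ref = grams[0]
    if not ref.is_square:
        raise MKLError("training Gram matrices must be square")
    for g in grams[1:]:
        if g.row_ids != ref.row_ids or g.col_ids != ref.col_ids:
            raise MKLError("Gram matrices are not aligned on the same sample ids")
    return grams


def _clean_weights(eta: np.ndarray) -> np.ndarray:
    eta = np.where(eta < WEIGHT_FLOOR, 0.0, eta)
    s = eta.sum()
    if s <= 0:
        raise MKLError("all kernel weights collapsed to zero")
    return eta / s


def _solve_at(grams, eta, y, C, tol=1e-6) -> SVMSolution:
    return solve_svm_dual(combine_grams(grams, eta), y, C, tol)


def _per_kernel_quadratics(grams, sol: SVMSolution) -> np.ndarray:
    """S_m = alpha' (yy' o K_m) alpha for each kernel."""
    ay = sol.alpha * sol.y
    return np.array([float(ay @ g.values @ ay) for g in grams])


def semkl_fit(
    grams: Sequence[GramMatrix],
    y: Sequence,
    C: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> MKLModel:
    """Simple and Efficient MKL: alternate SVM solves with the closed-form
    Cauchy-Schwarz weight update until max|delta eta| < tol."""
    grams = _check_grams(grams)
    M = len(grams)
    eta = np.full(M, 1.0 / M)
    trace = []
    converged = M == 1
    sol = _solve_at(grams, eta, y, C)
    if M > 1:
        for it in range(max_iter):
            S = _per_kernel_quadratics(grams, sol)
            norms = eta * np.sqrt(np.maximum(S, 0.0))  # ||f_m|| = eta_m sqrt(S_m)
            total = norms.sum()
            if total <= 0:
                raise MKLError(
                    "degenerate dual solution: all per-kernel function norms are zero "
                    f"(C={C}, objective={sol.objective:g})"
                )
            new_eta = _clean_weights(norms / total)
            delta = float(np.abs(new_eta - eta).max())
            trace.append({"eta": eta.copy(), "objective": sol.objective, "delta": delta})
            eta = new_eta
            sol = _solve_at(grams, eta, y, C)
            if delta < tol:
                converged = True
                break
        # boundary polish: the multiplicative update only reaches zero weights
        # asymptotically; try exact zeros for near-dead kernels and keep them
        # when the objective does not get worse
        tiny = (eta < 1e-2) & (eta > 0)
        if tiny.any() and not tiny.all():
            eta_z = np.where(tiny, 0.0, eta)
            eta_z = eta_z / eta_z.sum()
            sol_z = _solve_at(grams, eta_z, y, C)
            if sol_z.objective <= sol.objective:
                eta, sol = eta_z, sol_z
    trace.append({"eta": eta.copy(), "objective": sol.objective, "delta": 0.0})
    return MKLModel(
        weights=eta, svm=sol,
        specs=[g.spec for g in grams],
        trace=trace, converged=converged, method="semkl", C=C,
    )


def _reduced_direction(eta: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Reduced-gradient descent direction on the simplex.

    Pivot = largest-weight component (lowest index on ties); components at
    zero whose reduced gradient is positive are clipped to stay feasible.
    """
    mu = int(np.argmax(eta))  # argmax returns the lowest index on ties
    red = grad - grad[mu]
    d = -red
    d[(eta <= 0) & (d < 0)] = 0.0
    d[mu] = -(d.sum() - d[mu])
    return d


def _max_step(eta: np.ndarray, d: np.ndarray) -> float:
    neg = d < -1e-16
    if not np.any(neg):
        return 1.0
    return float(np.min(-eta[neg] / d[neg]))


def simplemkl_fit(
    grams: Sequence[GramMatrix],
    y: Sequence,
    C: float = 1.0,
    max_iter: int = 200,
    tol_gap: float = 0.01,
) -> MKLModel:
    """SimpleMKL: reduced-gradient descent with line search.

    ``max_iter`` caps the number of SVM solves (each line-search candidate
    step costs one solve).  Terminates when the relative duality gap
    (max_m S_m/2 - sum_m eta_m S_m/2) / |J| drops below ``tol_gap``.
    """
    grams = _check_grams(grams)
    M = len(grams)
    eta = np.full(M, 1.0 / M)
    sol = _solve_at(grams, eta, y, C)
    solves = 1
    trace = []
    converged = M == 1

    def objective_at(e):
        nonlocal solves
        solves += 1
        return _solve_at(grams, e, y, C)

    while M > 1 and solves < max_iter:
        S = _per_kernel_quadratics(grams, sol)
        J = sol.objective
        gap = (0.5 * S.max() - 0.5 * float(eta @ S)) / max(abs(J), 1e-12)
        trace.append({"eta": eta.copy(), "objective": J, "gap": gap})
        if gap < tol_gap:
            converged = True
            break
        grad = -0.5 * S
        d = _reduced_direction(eta, grad)
        if np.abs(d).max() < 1e-12:
            converged = True
            break
        t_max = _max_step(eta, d)
        step, new_sol = _line_search(objective_at, eta, d, t_max, J, lambda: max_iter - solves)
        if step is None:
            # no improving step found: report honestly and stop
            break
        eta = _clean_weights(eta + step * d)
        sol = new_sol if new_sol is not None else objective_at(eta)

    trace.append({"eta": eta.copy(), "objective": sol.objective, "gap": 0.0})
    return MKLModel(
        weights=eta, svm=sol,
        specs=[g.spec for g in grams],
        trace=trace, converged=converged, method="simplemkl", C=C,
    )


def _line_search(objective_at, eta, d, t_max, J0, budget, shrink=0.5):
    """Golden-section search on [0, t_max], Armijo backtracking fallback.

    Returns (step, SVMSolution at the step) or (None, None) when no
    improving step exists within the solve budget.
    """
    invphi = (np.sqrt(5.0) - 1) / 2

    def J(t):
        return objective_at(_clean_weights(eta + t * d))

    a, b = 0.0, t_max
    best_t, best_sol, best_J = None, None, J0
    # golden section: needs ~8 solves; skip straight to Armijo when tight
    if budget() > 10:
        c, dd = b - invphi * (b - a), a + invphi * (b - a)
        sc, sd = J(c), J(dd)
        for _ in range(6):
            if budget() <= 2:
                break
            if sc.objective < sd.objective:
                b, dd, sd = dd, c, sc
                c = b - invphi * (b - a)
                sc = J(c)
            else:
                a, c, sc = c, dd, sd
                dd = a + invphi * (b - a)
                sd = J(dd)
        for t, s in ((c, sc), (dd, sd)):
            if s.objective < best_J:
                best_t, best_sol, best_J = t, s, s.objective
        if best_t is not None:
            return best_t, best_sol
    # Armijo backtracking: accept the first improving step
    t = t_max
    while t > 1e-8 * max(t_max, 1.0) and budget() > 0:
        s = J(t)
        if s.objective < J0 - 1e-12 * abs(J0):
            return t, s
        t *= shrink
    return None, None


def mkl_predict(model: MKLModel, cross_grams: Sequence[GramMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Decision values and labels on new samples.

    ``cross_grams`` must be one rectangular (new x train) Gram per training
    kernel, in the same order.
    """
    cross_grams = list(cross_grams)
    if len(cross_grams) != len(model.weights):
        raise MKLError(
            f"model has {len(model.weights)} kernels but got {len(cross_grams)} cross-Grams"
        )
    combined = combine_grams(cross_grams, model.weights)
    return svm_predict(model.svm, combined)
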