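"""Synthetic data generators for exercising the MKL pipeline end to end.

Two generators are provided:

* a two-group bivariate Gaussian benchmark: group 1 fixed at mean (5, 5)
  with identity covariance, group 2 sweeping its mean over
  (-4,-4), (-3,-3), ..., (4,4) with covariance [[1, -0.5], [-0.5, 1]], so
  the amount of overlap between the groups varies across nine
  configurations.  MKL is run with two radial kernels (sigma = 2 and
  sigma = 0.04): as overlap grows, the wigglier sigma = 2 kernel should
  receive more weight, and held-out accuracy should fall from 1.0 towards
  chance.  An optional tenth configuration places group 2 exactly on group
  1's mean (completely overlapping groups, covariances still differ).

* a two-source clinical + expression dataset with a survival outcome: a
  binary outcome is driven by stage and age through a logistic link, a
  small number of expression features are mean-shifted between outcome
  groups, and survival times follow a two-component log-normal with
  independent censoring — the structure of a TCGA-style integration
  experiment at desk scale.

Every generator is a pure function of its config and seed; replicate seeds
are derived from (master seed, configuration index, replicate index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .kernels import GramMatrix, KernelSpec, compute_gram
from .mkl_dal import DALConfig, DALSolution, dal_predict, dalmkl_fit
from .mkl_wrappers import MKLModel, mkl_predict, semkl_fit, simplemkl_fit

SWEEP_METHODS = ("semkl", "simplemkl", "dal_hinge", "dal_logistic")


class SyntheticError(ValueError):
    pass


def _check_cov(S, name):
    S = np.asarray(S, dtype=float)
    if S.shape != (2, 2) or np.abs(S - S.T).max() > 1e-12:
        raise SyntheticError(f"{name} must be a symmetric 2x2 matrix")
    if np.linalg.eigvalsh(S)[0] <= 0:
        raise SyntheticError(f"{name} is not positive definite")
    return S


@dataclass(frozen=True)
class BenchmarkConfig:
    """Parameters of the two-group Gaussian benchmark sweep."""

    n_per_group: int = 50
    mean1: tuple = (5.0, 5.0)
    mean2_list: tuple = tuple((float(d), float(d)) for d in range(-4, 5))
    cov1: tuple = ((1.0, 0.0), (0.0, 1.0))
    cov2: tuple = ((1.0, -0.5), (-0.5, 1.0))
    sigma1: float = 2.0     # wiggly radial kernel K1
    sigma2: float = 0.04    # smooth radial kernel K2
    test_n_per_group: int = 50
    replicates: int = 30
    seed: int = 0
    include_overlap_config: bool = False  # append mean2 == mean1 as config 9

    def __post_init__(self):
        _check_cov(self.cov1, "cov1")
        _check_cov(self.cov2, "cov2")
        if self.n_per_group < 2 or self.test_n_per_group < 1:
            raise SyntheticError("group sizes too small")

    @property
    def mean2_all(self) -> list:
        means = [tuple(m) for m in self.mean2_list]
        if self.include_overlap_config:
            means.append(tuple(self.mean1))
        return means

    def kernel_specs(self) -> list[KernelSpec]:
        return [
            KernelSpec("radial", sigma=self.sigma1, name="K1"),
            KernelSpec("radial", sigma=self.sigma2, name="K2"),
        ]


def _draw_group_tables(rng, mean1, cov1, mean2, cov2, n, tag):
    x1 = rng.multivariate_normal(mean1, cov1, size=n)
    x2 = rng.multivariate_normal(mean2, cov2, size=n)
    X = pd.DataFrame(
        np.vstack([x1, x2]),
        columns=["x1", "x2"],
        index=[f"{tag}{i}" for i in range(2 * n)],
    )
    y = np.concatenate([np.full(n, 1.0), np.full(n, -1.0)])
    return X, y


def gen_two_gaussians(config: BenchmarkConfig, which_mean2: int, seed: int | None = None):
    """Draw independent train and test sets for one sweep configuration.

    Returns (X_train, y_train, X_test, y_test); group 1 is labelled +1.
    """
    means = config.mean2_all
    if not 0 <= which_mean2 < len(means):
        raise SyntheticError(f"which_mean2 must be in 0..{len(means) - 1}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, which_mean2])
    )
    m1, m2 = np.asarray(config.mean1, float), np.asarray(means[which_mean2], float)
    S1, S2 = np.asarray(config.cov1, float), np.asarray(config.cov2, float)
    Xtr, ytr = _draw_group_tables(rng, m1, S1, m2, S2, config.n_per_group, "tr")
    Xte, yte = _draw_group_tables(rng, m1, S1, m2, S2, config.test_n_per_group, "te")
    return Xtr, ytr, Xte, yte


def fit_mkl_method(
    method: str,
    train_grams: Sequence[GramMatrix],
    y,
    wrapper_C: float = 1.0,
    dal_C: float = 0.05,
    **kwargs,
):
    """Dispatch one of the four MKL solvers by name.

    Returns an object with ``.weights`` and a matching predict function via
    :func:`predict_mkl_method`.
    """
    if method == "semkl":
        return semkl_fit(train_grams, y, C=wrapper_C, **kwargs)
    if method == "simplemkl":
        return simplemkl_fit(train_grams, y, C=wrapper_C, **kwargs)
    if method in ("dal_hinge", "dal_logistic"):
        loss = method.split("_", 1)[1]
        return dalmkl_fit(train_grams, y, DALConfig(loss=loss, C=dal_C, **kwargs))
    raise SyntheticError(f"unknown method {method!r}; expected one of {SWEEP_METHODS}")


def predict_mkl_method(model, cross_grams: Sequence[GramMatrix]):
    if isinstance(model, DALSolution):
        return dal_predict(model, cross_grams)
    return mkl_predict(model, cross_grams)


def benchmark_sweep(
    config: BenchmarkConfig,
    methods: Sequence[str] = SWEEP_METHODS,
    wrapper_C: float = 1.0,
    dal_C: float = 0.05,
) -> pd.DataFrame:
    """Full factorial benchmark: configuration x method x replicate.

    Returns a tidy DataFrame with one row per cell: the learned weight of
    the sigma = 2 kernel (K1), train/test accuracy, and the replicate seed.
    Solver failures are recorded (``error`` column) and the sweep continues.
    """
    for m in methods:
        if m not in SWEEP_METHODS:
            raise SyntheticError(f"unknown method {m!r}")
    specs = config.kernel_specs()
    rows = []
    for ci, mean2 in enumerate(config.mean2_all):
        for rep in range(config.replicates):
            seq = np.random.SeedSequence([config.seed, ci, rep])
            rep_seed = int(seq.generate_state(1)[0] % (2**31))
            Xtr, ytr, Xte, yte = gen_two_gaussians(config, ci, seed=rep_seed)
            train_grams = [compute_gram(Xtr, Xtr, s) for s in specs]
            cross_grams = [compute_gram(Xte, Xtr, s) for s in specs]
            for method in methods:
                row = {
                    "config_index": ci,
                    "mean2": f"({mean2[0]:g},{mean2[1]:g})",
                    "overlap_rank": ci,
                    "method": method,
                    "replicate": rep,
                    "seed": rep_seed,
                    "weight_K1": np.nan,
                    "train_acc": np.nan,
                    "test_acc": np.nan,
                    "error": "",
                }
                try:
                    model = fit_mkl_method(method, train_grams, ytr,
                                           wrapper_C=wrapper_C, dal_C=dal_C)
                    _, pred_tr = predict_mkl_method(model, train_grams)
                    _, pred_te = predict_mkl_method(model, cross_grams)
                    row["weight_K1"] = float(model.weights[0])
                    row["train_acc"] = float(np.mean(pred_tr == ytr))
                    row["test_acc"] = float(np.mean(pred_te == yte))
                except Exception as exc:  # recorded, sweep continues
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_sweep(results: pd.DataFrame) -> pd.DataFrame:
    """Mean K1 weight and accuracy per configuration x method."""
    ok = results[results["error"] == ""]
    return (
        ok.groupby(["config_index", "mean2", "method"], as_index=False)
        .agg(
            mean_weight_K1=("weight_K1", "mean"),
            mean_test_acc=("test_acc", "mean"),
            mean_train_acc=("train_acc", "mean"),
            n=("replicate", "size"),
        )
        .sort_values(["config_index", "method"], ignore_index=True)
    )


@dataclass(frozen=True)
class OmicsSimConfig:
    """Parameters of the two-source clinical + expression generator."""

    n: int = 200
    p: int = 300
    n_informative: int = 10
    effect: float = 0.8          # mean shift between outcome groups, in sd units
    stage_levels: int = 4
    stage_coef: float = 0.8      # logistic coefficient per stage level
    age_coef: float = 0.8        # logistic coefficient per sd of age
    surv_logmean_good: float = np.log(60.0)   # months, survivors
    surv_logmean_poor: float = np.log(20.0)
    surv_logsd: float = 0.5
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.n_informative <= self.p:
            raise SyntheticError("need 0 < n_informative <= p")
        if not 0 <= self.censoring_rate < 1:
            raise SyntheticError("censoring rate must be in [0, 1)")
        if self.effect < 0:
            raise SyntheticError("effect size must be nonnegative")
        if self.n_informative > 0 and self.effect == 0:
            raise SyntheticError("informative features requested with zero effect")


def gen_multiomics(config: OmicsSimConfig, seed: int | None = None) -> dict:
    """Generate a linked clinical + expression + survival dataset.

    Returns a dict with keys ``expression`` (n x p DataFrame),
    ``clinical`` (stage, age), ``survival`` (time, event), ``outcome``
    (true binary labels in {-1, +1}; +1 = good prognosis) and
    ``informative`` (the ground-truth informative gene ids).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, p = config.n, config.p
    ids = [f"s{i}" for i in range(n)]

    stage = rng.integers(1, config.stage_levels + 1, size=n).astype(float)
    age = rng.normal(0.0, 1.0, size=n)
    # higher stage / age -> worse prognosis
    lp = -config.stage_coef * (stage - (config.stage_levels + 1) / 2) - config.age_coef * age
    z = np.where(rng.random(n) < 1.0 / (1.0 + np.exp(-lp)), 1.0, -1.0)

    expr = rng.normal(0.0, 1.0, size=(n, p))
    informative = [f"g{j}" for j in range(config.n_informative)]
    expr[:, : config.n_informative] += (config.effect / 2.0) * z[:, None]
    expression = pd.DataFrame(expr, index=ids, columns=[f"g{j}" for j in range(p)])

    logmean = np.where(z > 0, config.surv_logmean_good, config.surv_logmean_poor)
    t_true = rng.lognormal(mean=logmean, sigma=config.surv_logsd)
    censored = rng.random(n) < config.censoring_rate
    t_obs = np.where(censored, rng.uniform(0, 1, n) * t_true, t_true)
    t_obs = np.maximum(t_obs, 1e-6)

    clinical = pd.DataFrame({"stage": stage, "age": age}, index=ids)
    survival = pd.DataFrame(
        {"time": t_obs, "event": (~censored).astype(int)}, index=ids
    )
    return {
        "expression": expression,
        "clinical": clinical,
        "survival": survival,
        "outcome": pd.Series(z, index=ids, name="outcome"),
        "informative": informative,
    }


def gen_noise_kernel_problem(
    seed: int,
    n: int = 60,
    n_blocks: int = 10,
    block_size: int = 5,
    n_informative_blocks: int = 2,
    effect: float = 2.0,
):
    """Kernel-selection positive control: mostly-noise kernel menu.

    Builds ``n_blocks`` disjoint radial kernels over ``block_size`` features
    each; features in the first ``n_informative_blocks`` blocks are shifted
    by ``effect`` standard deviations between the two classes (a strong,
    clearly informative signature), the rest are pure noise.  Used to check
    that the sparse solver keeps the informative kernels active and zeroes
    the noise kernels exactly.

    Returns (table, labels, specs, informative_block_indices).
    """
    if n_informative_blocks > n_blocks:
        raise SyntheticError("more informative blocks than blocks")
    rng = np.random.default_rng(seed)
    y = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    X = rng.normal(size=(n, n_blocks * block_size))
    for b in range(n_informative_blocks):
        X[:, b * block_size:(b + 1) * block_size] += (effect / 2.0) * y[:, None]
    table = pd.DataFrame(
        X, index=[f"s{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(n_blocks * block_size)],
    )
    specs = [
        KernelSpec(
            "radial",
            sigma=1.0 / block_size,
            feature_subset=tuple(f"f{j}" for j in range(b * block_size, (b + 1) * block_size)),
            name=f"block{b}",
        )
        for b in range(n_blocks)
    ]
    return table, y, specs, list(range(n_informative_blocks))
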