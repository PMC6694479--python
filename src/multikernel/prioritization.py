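"""Feature and kernel prioritization for the MKL workflow.

Stages of the recommended workflow implemented here:

1. rank features by a two-group test (Welch t or Wilcoxon rank-sum) and
   keep the top k — SVM suffers from the curse of dimensionality when only
   a handful of features separate the classes;
2. screen candidate kernels: cross-validate an SVM per candidate and drop
   those whose best accuracy does not beat the no-information rate (NIR);
   survivors carry their best hyperparameters into MKL;
3. build one kernel per gene set (GMT) restricted to the measured genes;
4. dichotomize a survival outcome: drop right-censored patients, then pick
   an event-time cutoff whose survivor proportion lies in a target band.

All operations accept *training* rows only; selecting features or kernels
on data that includes test samples leaks the held-out outcome into the
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import KernelSpec
from .svm_core import (
    CVResult,
    DEFAULT_C_GRID,
    SVMError,
    cross_validate_svm,
    no_information_rate,
)

logger = logging.getLogger("multikernel")


class PrioritizationError(RuntimeError):
    pass


@dataclass
class FeatureRanking:
    """Features ordered by ascending p-value (ties broken by feature id)."""

    table: pd.DataFrame     # index: feature id; columns: statistic, pvalue, flagged
    method: str

    @property
    def ordered_features(self) -> list:
        return list(self.table.index)

    @property
    def pvalues(self) -> pd.Series:
        return self.table["pvalue"]


def rank_features(X: pd.DataFrame, y: Sequence, method: str = "t") -> FeatureRanking:
    """Per-feature two-group comparison; 't' = Welch t-test, 'wilcoxon' =
    Wilcoxon rank-sum (Mann-Whitney).

    Constant features get p = 1 and are flagged rather than dropped.
    """
    if method not in ("t", "wilcoxon"):
        raise PrioritizationError(f"unknown ranking method {method!r}")
    y = np.asarray(y)
    groups = np.unique(y)
    if groups.size != 2:
        raise PrioritizationError(f"need exactly two groups, got {groups.size}")
    m0, m1 = y == groups[0], y == groups[1]
    if m0.sum() < 2 or m1.sum() < 2:
        raise PrioritizationError("need >= 2 samples per class")
    A = X.loc[m0].to_numpy(float)
    B = X.loc[m1].to_numpy(float)

    constant = np.array([np.ptp(X[c].to_numpy(float)) == 0 for c in X.columns])
    stat = np.full(X.shape[1], 0.0)
    pval = np.ones(X.shape[1])
    var_ok = ~constant
    if var_ok.any():
        if method == "t":
            res = stats.ttest_ind(A[:, var_ok], B[:, var_ok], equal_var=False)
            stat[var_ok], pval[var_ok] = res.statistic, res.pvalue
        else:
            res = stats.mannwhitneyu(A[:, var_ok], B[:, var_ok], alternative="two-sided")
            stat[var_ok], pval[var_ok] = res.statistic, res.pvalue
    pval = np.where(np.isnan(pval), 1.0, pval)
    if constant.any():
        logger.warning("%d constant feature(s) flagged with p = 1", int(constant.sum()))

    table = pd.DataFrame(
        {"statistic": stat, "pvalue": pval, "flagged": constant},
        index=X.columns,
    )
    # stable ordering: ascending p, ties broken by feature id
    table = table.iloc[np.lexsort((table.index.astype(str), table["pvalue"].to_numpy()))]
    return FeatureRanking(table=table, method=method)


def select_top_features(ranking: FeatureRanking, k: int) -> list:
    """First k feature ids in ranking order (prefix-consistent in k)."""
    n = len(ranking.table)
    if k <= 0 or k > n:
        raise PrioritizationError(f"k must be in 1..{n}, got {k}")
    return ranking.ordered_features[:k]


@dataclass
class ScreeningResult:
    survivors: list                  # KernelSpec with best hyperparameters resolved
    survivor_C: list                 # matched best C per survivor
    table: pd.DataFrame              # per-candidate best accuracy and verdict
    nir: float
    cv_results: list = field(default_factory=list)


def screen_kernels(
    X: pd.DataFrame,
    y: Sequence,
    candidates: Sequence[KernelSpec],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 10,
    seed: int = 0,
) -> ScreeningResult:
    """Cross-validate each candidate kernel and eliminate the uninformative.

    A candidate survives only when its best cross-validated accuracy is
    strictly greater than the no-information rate; accuracy equal to the
    NIR is the signature of a classifier collapsed onto the majority class
    and is eliminated.  Raises when no candidate survives.
    """
    nir = no_information_rate(y)
    rows, survivors, survivor_C, cv_results = [], [], [], []
    for spec in candidates:
        cv = cross_validate_svm(X, y, [spec], C_grid=C_grid, k=folds, seed=seed)
        cv_results.append(cv)
        keep = cv.best_acc > nir
        rows.append(
            {"kernel": spec.label, "best_C": cv.best_C, "best_acc": cv.best_acc,
             "nir": nir, "survives": keep}
        )
        if keep:
            survivors.append(spec)
            survivor_C.append(cv.best_C)
        else:
            logger.info("kernel %s eliminated (acc %.3f <= NIR %.3f)", spec.label, cv.best_acc, nir)
    if not survivors:
        raise PrioritizationError(
            f"no surviving kernels: all {len(list(candidates))} candidates scored <= NIR ({nir:.3f})"
        )
    return ScreeningResult(
        survivors=survivors, survivor_C=survivor_C,
        table=pd.DataFrame(rows), nir=nir, cv_results=cv_results,
    )


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict                      # name -> tuple of gene ids
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.sets) != len(set(self.sets)):
            raise PrioritizationError("gene set names must be unique")

    def __len__(self):
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        """Read a GMT file: tab-separated name, description, gene ids."""
        sets, desc = {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise PrioritizationError(
                        f"malformed GMT line (need name, description, >=1 gene): {line[:60]!r}"
                    )
                name = parts[0]
                if name in sets:
                    raise PrioritizationError(f"duplicate gene set name {name!r}")
                genes = tuple(g for g in parts[2:] if g)
                if not genes:
                    raise PrioritizationError(f"gene set {name!r} is empty")
                sets[name], desc[name] = genes, parts[1]
        if not sets:
            raise PrioritizationError(f"no gene sets found in {path}")
        return cls(sets=sets, descriptions=desc)


def geneset_kernel_specs(
    expression_genes: Sequence[str],
    sets: GeneSetCollection,
    base: KernelSpec,
) -> list[KernelSpec]:
    """One KernelSpec per gene set, restricted to the measured genes.

    Sets with no measured genes are dropped (with a warning count); raises
    when every set is empty after intersection.
    """
    measured = set(expression_genes)
    specs, dropped = [], 0
    for name, genes in sets.sets.items():
        subset = [g for g in genes if g in measured]  # keep GMT order
        if not subset:
            dropped += 1
            continue
        specs.append(_named(base.with_subset(subset), name))
    if dropped:
        logger.warning("%d gene set(s) dropped: no measured genes", dropped)
    if not specs:
        raise PrioritizationError("all gene sets are empty after intersecting with measured genes")
    return specs


def _named(spec: KernelSpec, name: str) -> KernelSpec:
    from dataclasses import replace

    return replace(spec, name=name)


def dichotomize_survival(
    time: Sequence[float],
    event: Sequence[int],
    lo: float = 0.4,
    hi: float = 0.6,
    min_kept: int = 10,
    ids: Sequence | None = None,
) -> tuple[np.ndarray, float, list]:
    """Binary survival outcome from (time, event) columns.

    Right-censored patients (event == 0) are excluded first.  Candidate
    cutoffs are midpoints between consecutive distinct event times; feasible
    cutoffs give a survivor proportion (time > cutoff) within [lo, hi], and
    among those the proportion closest to 0.5 wins (ties -> smaller cutoff).
    Returns (labels in {-1, +1} with +1 = survived past cutoff, cutoff,
    kept ids).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape:
        raise PrioritizationError("time and event must have the same length")
    if np.any(time <= 0):
        raise PrioritizationError("survival times must be positive")
    if not (0 < lo < hi < 1):
        raise PrioritizationError(f"need 0 < lo < hi < 1, got ({lo}, {hi})")
    ids = list(ids) if ids is not None else list(range(time.size))

    keep = event != 0
    t_kept = time[keep]
    kept_ids = [i for i, k in zip(ids, keep) if k]
    n = t_kept.size
    if n < min_kept:
        raise PrioritizationError(
            f"only {n} uncensored patients (< min_kept={min_kept})"
        )
    uniq = np.unique(t_kept)
    if uniq.size < 2:
        raise PrioritizationError("all events at the same time: no feasible cutoff")
    cutoffs = 0.5 * (uniq[:-1] + uniq[1:])
    props = np.array([(t_kept > c).mean() for c in cutoffs])
    feasible = (props >= lo) & (props <= hi)
    if not feasible.any():
        raise PrioritizationError(
            f"no cutoff gives a survivor proportion in [{lo}, {hi}] "
            f"(closest achievable: {props[np.abs(props - 0.5).argmin()]:.3f})"
        )
    idx = np.flatnonzero(feasible)
    best = idx[np.argmin(np.abs(props[idx] - 0.5), )]  # ties -> smaller cutoff
    cutoff = float(cutoffs[best])
    labels = np.where(t_kept > cutoff, 1.0, -1.0)
    return labels, cutoff, kept_ids


def median_heuristic_sigma(X: pd.DataFrame | np.ndarray) -> float:
    """Radial bandwidth from the median pairwise squared distance.

    Returns sigma such that the kernel exp(-sigma d^2 / 2) has exponent 1/2
    at the median squared distance (sigma = 1 / median(d^2)).
    """
    x = np.asarray(X, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    from sklearn.metrics.pairwise import euclidean_distances

    d2 = euclidean_distances(x, x, squared=True)
    med = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    if med <= 0:
        raise PrioritizationError("median pairwise distance is zero; cannot set bandwidth")
    return 1.0 / med


def ovarian_preset(
    expression_features: Sequence[str],
    stage_feature: str,
    age_feature: str,
    n_stage_levels: int,
    age_sigma: float,
) -> dict:
    """Kernel menu used for the ovarian-style two-source analysis.

    Expression candidates: linear plus radial kernels with sigma in
    {1e-4, 1e-3, 1e-2}.  Clinical candidates: ordinal kernel on tumour
    stage, radial kernel on (standardized) age, and their equal-weight
    average expressed as a combined kernel downstream.
    """
    expr = list(expression_features)
    expression = [KernelSpec("linear", feature_subset=expr, name="expr:linear")]
    expression += [
        KernelSpec("radial", sigma=s, feature_subset=expr, name=f"expr:radial:{s:g}")
        for s in (1e-4, 1e-3, 1e-2)
    ]
    clinical = [
        KernelSpec("clinical_ordinal", r=float(n_stage_levels - 1),
                   feature_subset=(stage_feature,), name="clin:stage"),
        KernelSpec("radial", sigma=age_sigma, feature_subset=(age_feature,), name="clin:age"),
    ]
    return {"expression": expression, "clinical": clinical}
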