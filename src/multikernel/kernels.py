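"""Kernel (Gram matrix) construction for mixed clinical and omics data.

Five kernel families are supported, covering the continuous similarities
used for expression-type data (linear, polynomial, radial) and the two
clinical similarities for categorical covariates:

* linear:           K(x, y) = <x, y>
* polynomial:       K(x, y) = (nu * <x, y> + offset)^a
* radial:           K(x, y) = exp(-sigma * ||x - y||^2 / 2)
* clinical_nominal: K(x, y) = 1 if x == y else 0
* clinical_ordinal: K(x, y) = (r - |x - y|) / r

A :class:`KernelSpec` declares one kernel (family, hyperparameters and the
feature subset it reads); :func:`compute_gram` evaluates it between two
sample tables into a :class:`GramMatrix`.  Convex combinations of Gram
matrices — the object multiple kernel learning optimizes over — are formed
with :func:`combine_grams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import euclidean_distances

logger = logging.getLogger("multikernel")

KERNEL_KINDS = ("linear", "polynomial", "radial", "clinical_nominal", "clinical_ordinal")

#: symmetry tolerance for square Gram matrices
SYMMETRY_TOL = 1e-10
#: a square Gram is accepted as PSD when lambda_min >= -PSD_RTOL * lambda_max
PSD_RTOL = 1e-8


class KernelError(ValueError):
    """Invalid kernel specification or incompatible inputs."""


@dataclass(frozen=True)
class KernelSpec:
    """Declarative description of a single kernel.

    Parameters
    ----------
    kind
        One of ``linear``, ``polynomial``, ``radial``, ``clinical_nominal``,
        ``clinical_ordinal``.
    degree
        Polynomial degree ``a`` (>= 1, polynomial only).
    scale
        Polynomial coefficient ``nu`` (> 0, polynomial only).
    offset
        Polynomial offset (polynomial only).
    sigma
        Radial width ``sigma`` (> 0, radial only); larger sigma gives a
        wigglier decision boundary.
    r
        Range of the ordinal levels (> 0, ordinal only).
    feature_subset
        Feature names the kernel reads; empty tuple means all columns.
    normalize
        Cosine-normalize the Gram matrix (linear/polynomial only).
    kernlab_convention
        Use exp(-sigma*||x-y||^2) (the kernlab ``rbfdot`` convention)
        instead of the default exp(-sigma*||x-y||^2 / 2).
    name
        Optional label used in reports; defaults to a description of the
        hyperparameters.
    """

    kind: str
    degree: int | None = None
    scale: float | None = None
    offset: float | None = None
    sigma: float | None = None
    r: float | None = None
    feature_subset: tuple = ()
    normalize: bool = False
    kernlab_convention: bool = False
    name: str | None = None

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise KernelError(f"unknown kernel kind {self.kind!r}; expected one of {KERNEL_KINDS}")
        if self.kind == "polynomial":
            object.__setattr__(self, "degree", 1 if self.degree is None else int(self.degree))
            object.__setattr__(self, "scale", 1.0 if self.scale is None else float(self.scale))
            object.__setattr__(self, "offset", 0.0 if self.offset is None else float(self.offset))
            if self.degree < 1:
                raise KernelError(f"polynomial degree must be >= 1, got {self.degree}")
            if self.scale <= 0:
                raise KernelError(f"polynomial scale nu must be > 0, got {self.scale}")
        elif self.kind == "radial":
            if self.sigma is None or self.sigma <= 0:
                raise KernelError(f"radial kernel requires sigma > 0, got {self.sigma}")
        elif self.kind == "clinical_ordinal":
            if self.r is not None and self.r <= 0:
                raise KernelError(f"ordinal range r must be > 0, got {self.r}")
        extraneous = {
            "linear": ("degree", "scale", "offset", "sigma", "r"),
            "polynomial": ("sigma", "r"),
            "radial": ("degree", "scale", "offset", "r"),
            "clinical_nominal": ("degree", "scale", "offset", "sigma", "r"),
            "clinical_ordinal": ("degree", "scale", "offset", "sigma"),
        }[self.kind]
        for f in extraneous:
            if getattr(self, f) is not None:
                raise KernelError(f"hyperparameter {f!r} is not valid for kind {self.kind!r}")
        if self.normalize and self.kind not in ("linear", "polynomial"):
            raise KernelError("normalize is only supported for linear/polynomial kernels")
        object.__setattr__(self, "feature_subset", tuple(self.feature_subset))

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        bits = [self.kind]
        if self.kind == "polynomial":
            bits.append(f"a={self.degree},nu={self.scale},offset={self.offset}")
        elif self.kind == "radial":
            bits.append(f"sigma={self.sigma:g}")
        elif self.kind == "clinical_ordinal" and self.r is not None:
            bits.append(f"r={self.r:g}")
        if self.feature_subset:
            bits.append(f"{len(self.feature_subset)}feat")
        return ":".join(bits)

    def with_subset(self, features: Sequence[str]) -> "KernelSpec":
        return replace(self, feature_subset=tuple(features))

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for f in ("degree", "scale", "offset", "sigma", "r", "name"):
            v = getattr(self, f)
            if v is not None:
                d[f] = v
        if self.feature_subset:
            d["feature_subset"] = list(self.feature_subset)
        if self.normalize:
            d["normalize"] = True
        if self.kernlab_convention:
            d["kernlab_convention"] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        d = dict(d)
        d["feature_subset"] = tuple(d.get("feature_subset", ()))
        return cls(**d)


@dataclass
class GramMatrix:
    """A similarity matrix between two sample sets.

    Square and symmetric when ``row_ids == col_ids`` (training); rectangular
    (test rows x training columns) for prediction.
    """

    values: np.ndarray
    row_ids: tuple
    col_ids: tuple
    spec: KernelSpec | str = "combined"
    weights: np.ndarray | None = None  # set by combine_grams

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = tuple(self.row_ids)
        self.col_ids = tuple(self.col_ids)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise KernelError(
                f"Gram shape {self.values.shape} does not match ids "
                f"({len(self.row_ids)} x {len(self.col_ids)})"
            )

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids), columns=list(self.col_ids))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, spec: KernelSpec | str = "combined") -> "GramMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), tuple(df.index), tuple(df.columns), spec)


def _subset(table: pd.DataFrame, spec: KernelSpec) -> pd.DataFrame:
    if not spec.feature_subset:
        return table
    missing = [f for f in spec.feature_subset if f not in table.columns]
    if missing:
        raise KernelError(f"features not found in table: {missing[:5]}")
    return table.loc[:, list(spec.feature_subset)]


def _numeric_matrix(table: pd.DataFrame, spec: KernelSpec) -> np.ndarray:
    try:
        x = table.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise KernelError(f"non-numeric input for {spec.kind} kernel: {exc}") from None
    if not np.all(np.isfinite(x)):
        raise KernelError(f"non-finite values in input table for {spec.kind} kernel")
    return x


def compute_gram(rows: pd.DataFrame, cols: pd.DataFrame, spec: KernelSpec) -> GramMatrix:
    """Evaluate ``spec`` between every row of ``rows`` and every row of ``cols``.

    Both tables are sample-by-feature DataFrames indexed by sample id.  The
    kernel is restricted to ``spec.feature_subset`` when given.
    """
    xr, xc = _subset(rows, spec), _subset(cols, spec)
    kind = spec.kind

    if kind in ("linear", "polynomial", "radial"):
        a = _numeric_matrix(xr, spec)
        b = _numeric_matrix(xc, spec)
        if kind == "linear":
            K = a @ b.T
        elif kind == "polynomial":
            K = (spec.scale * (a @ b.T) + spec.offset) ** spec.degree
        else:  # radial
            d2 = euclidean_distances(a, b, squared=True)
            np.maximum(d2, 0.0, out=d2)
            scale = spec.sigma if spec.kernlab_convention else spec.sigma / 2.0
            K = np.exp(-scale * d2)
        if spec.normalize:
            # cosine normalization K_ij / sqrt(K_ii K_jj), diagonals from self-grams
            dr = _self_diag(a, spec)
            dc = _self_diag(b, spec)
            denom = np.sqrt(np.outer(dr, dc))
            if np.any(denom <= 0):
                raise KernelError("cosine normalization undefined: zero self-similarity")
            K = K / denom
    elif kind == "clinical_nominal":
        K = _nominal_gram(xr, xc)
    else:  # clinical_ordinal
        a = _numeric_matrix(xr, spec)
        b = _numeric_matrix(xc, spec)
        K = _ordinal_gram(a, b, spec)

    gram = GramMatrix(K, rows.index, cols.index, spec)
    if gram.is_square:
        # enforce exact symmetry on numerically symmetric output
        asym = np.abs(gram.values - gram.values.T).max() if gram.values.size else 0.0
        if asym > SYMMETRY_TOL * max(1.0, np.abs(gram.values).max()):
            raise KernelError(f"computed square Gram is not symmetric (max asymmetry {asym:g})")
        gram.values = 0.5 * (gram.values + gram.values.T)
    return gram


def _self_diag(x: np.ndarray, spec: KernelSpec) -> np.ndarray:
    s = np.einsum("ij,ij->i", x, x)
    if spec.kind == "polynomial":
        return (spec.scale * s + spec.offset) ** spec.degree
    return s


def _nominal_gram(xr: pd.DataFrame, xc: pd.DataFrame) -> np.ndarray:
    # exact-match indicator per feature, averaged over the subset so that
    # multi-feature nominal kernels stay in [0, 1]
    n, m = len(xr), len(xc)
    K = np.zeros((n, m))
    for col in xr.columns:
        a = xr[col].to_numpy()
        b = xc[col].to_numpy()
        K += (a[:, None] == b[None, :]).astype(float)
    return K / max(1, xr.shape[1])


def _ordinal_gram(a: np.ndarray, b: np.ndarray, spec: KernelSpec) -> np.ndarray:
    K = np.zeros((a.shape[0], b.shape[0]))
    for j in range(a.shape[1]):
        lo = min(a[:, j].min(), b[:, j].min())
        hi = max(a[:, j].max(), b[:, j].max())
        r = spec.r if spec.r is not None else max(hi - lo, 1.0)
        if hi - lo > r + 1e-12:
            raise KernelError(
                f"ordinal levels span {hi - lo:g}, exceeding declared range r={r:g}"
            )
        K += (r - np.abs(a[:, j, None] - b[None, :, j])) / r
    return K / max(1, a.shape[1])


def encode_ordinal(levels: Sequence, order: Sequence) -> np.ndarray:
    """Map ordinal labels to consecutive integer codes 0..len(order)-1."""
    lut = {lvl: i for i, lvl in enumerate(order)}
    try:
        return np.array([lut[v] for v in levels], dtype=float)
    except KeyError as exc:
        raise KernelError(f"ordinal level {exc.args[0]!r} not in declared order {list(order)}") from None


def combine_grams(grams: Sequence[GramMatrix], weights: Sequence[float]) -> GramMatrix:
    """Weighted sum ``sum_m eta_m K_m`` of aligned Gram matrices.

    A convex combination of PSD kernels is again a kernel; this is the
    combined similarity an MKL model classifies with.
    """
    grams = list(grams)
    w = np.asarray(weights, dtype=float)
    if len(grams) == 0:
        raise KernelError("no Gram matrices to combine")
    if w.shape != (len(grams),):
        raise KernelError(f"got {len(grams)} grams but {w.size} weights")
    if np.any(w < 0):
        raise KernelError(f"negative kernel weight: {w.min()}")
    ref = grams[0]
    for g in grams[1:]:
        if g.row_ids != ref.row_ids or g.col_ids != ref.col_ids:
            raise KernelError("Gram matrices are not aligned on the same sample ids")
    values = np.zeros(ref.shape)
    for g, wm in zip(grams, w):
        if wm != 0.0:
            values += wm * g.values
    out = GramMatrix(values, ref.row_ids, ref.col_ids, "combined")
    out.weights = w
    return out


def validate_psd(gram: GramMatrix, jitter: float = 1e-8) -> GramMatrix:
    """Check a square Gram for positive semidefiniteness; repair with jitter.

    Returns the input unchanged when the smallest eigenvalue is >=
    ``-PSD_RTOL * lambda_max``; otherwise adds ``jitter * I`` (escalating by
    powers of ten up to 1e-2) and logs the repair.
    """
    if not gram.is_square:
        raise KernelError("validate_psd requires a square Gram matrix")
    vals = 0.5 * (gram.values + gram.values.T)
    eig = np.linalg.eigvalsh(vals)
    lmin, lmax = eig[0], max(eig[-1], 0.0)
    if lmin >= -PSD_RTOL * max(lmax, 1.0):
        return gram
    j = jitter
    while j <= 1e-2:
        if lmin + j >= -PSD_RTOL * max(lmax, 1.0):
            logger.warning(
                "Gram (%s) not PSD (lambda_min=%.3e); repaired with %.1e * I",
                gram.spec if isinstance(gram.spec, str) else gram.spec.label, lmin, j,
            )
            out = GramMatrix(vals + j * np.eye(vals.shape[0]), gram.row_ids, gram.col_ids, gram.spec)
            out.weights = gram.weights
            return out
        j *= 10
    raise KernelError(f"Gram matrix is far from PSD (lambda_min={lmin:g}); jitter repair failed")
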