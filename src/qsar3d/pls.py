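"""PLS regression on field descriptors with leave-one-out cross-validation.

Preprocessing follows the conventional CoMFA treatment: columns whose
training-set standard deviation falls below a filter threshold (default
2.0, in the column's native units) are dropped, and each field block is
scaled by the inverse of its overall standard deviation ("CoMFA-STD" block
scaling) so that no block dominates by sheer magnitude.

The latent-variable regression itself is NIPALS partial least squares
(scikit-learn's implementation, no per-column autoscaling).  Model quality
is summarized with the standard internal statistics:

* q² = 1 − PRESS / Σ(y_i − ȳ)², with leave-one-out predictions and ȳ the
  full training-set mean;
* SEP = √(PRESS / (n − N − 1)) and SEE = √(RSS / (n − N − 1));
* r²_ncv = 1 − RSS/TSS and F = (r²/N) / ((1 − r²)/(n − N − 1));
* per-field contribution: Σ_j |coef_j|·sd_j over each block's retained
  columns, normalized across blocks (invariant to block rescaling).

The optimal component count maximizes q² (ties towards fewer components)
and is capped at ⌊n/3⌋ to avoid overtrained models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fields import DescriptorMatrix

__all__ = [
    "PreprocessSpec",
    "Preprocessor",
    "PLSModel",
    "PLSModelSummary",
    "filter_columns",
    "pls_fit",
    "loo_q2",
    "summarize_model",
]


@dataclass(frozen=True)
class PreprocessSpec:
    column_filter_threshold: float = 2.0
    scaling: str = "comfa_std"  # or "none"

    def __post_init__(self) -> None:
        if self.column_filter_threshold < 0:
            raise ValueError("column filter threshold must be >= 0")
        if self.scaling not in ("comfa_std", "none"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


def filter_columns(
    matrix: DescriptorMatrix, threshold: float
) -> tuple[DescriptorMatrix, np.ndarray]:
    """Drop columns with (sample) standard deviation below ``threshold``.

    Returns the filtered matrix and the indices of the dropped columns.
    A threshold of 0 drops nothing.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold == 0:
        return matrix, np.array([], dtype=int)
    sds = np.std(matrix.X, axis=0, ddof=1)
    keep = sds >= threshold
    if not keep.any():
        raise ValueError(
            "column filter dropped every descriptor column; lower the threshold"
        )
    dropped = np.flatnonzero(~keep)
    return matrix.select_columns(np.flatnonzero(keep)), dropped


class Preprocessor:
    """Column filter + block scaling, fit on a training matrix."""

    def __init__(self, spec: PreprocessSpec | None = None):
        self.spec = spec or PreprocessSpec()
        self.keep_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None  # per retained column
        self.field_types_: np.ndarray | None = None
        self.grid_indices_: np.ndarray | None = None

    def fit(self, matrix: DescriptorMatrix) -> "Preprocessor":
        X = matrix.X
        if self.spec.column_filter_threshold > 0:
            sds = np.std(X, axis=0, ddof=1)
            keep = sds >= self.spec.column_filter_threshold
            if not keep.any():
                raise ValueError(
                    "column filter dropped every descriptor column; lower the threshold"
                )
        else:
            keep = np.ones(X.shape[1], dtype=bool)
        self.keep_ = keep
        self.field_types_ = matrix.field_types[keep]
        self.grid_indices_ = matrix.grid_indices[keep]
        scale = np.ones(int(keep.sum()))
        if self.spec.scaling == "comfa_std":
            for ft in dict.fromkeys(self.field_types_):
                cols = self.field_types_ == ft
                block = X[:, keep][:, cols]
                sd = float(np.std(block, ddof=1))
                if sd > 0:
                    scale[cols] = 1.0 / sd
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.keep_ is None:
            raise RuntimeError("Preprocessor not fitted")
        return X[:, self.keep_] * self.scale_


class PLSModel:
    """NIPALS PLS wrapper exposing coefficients in the input column space."""

    def __init__(self, n_components: int):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = n_components
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSModel":
        from sklearn.cross_decomposition import PLSRegression

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if self.n_components > min(n - 1, p):
            raise ValueError(
                f"cannot extract {self.n_components} components from a {n}x{p} matrix"
            )
        pls = PLSRegression(n_components=self.n_components, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(X, y)
        coef = np.asarray(pls.coef_).reshape(-1)
        if not np.all(np.isfinite(coef)):
            raise ValueError("PLS fit did not converge (rank-deficient component request?)")
        self.coef_ = coef
        # sklearn's intercept_ applies to centered X; fold the centering in
        self.intercept_ = float(y.mean() - X.mean(axis=0) @ coef)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model not fitted")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit NIPALS PLS with ``n_components`` latent variables."""
    return PLSModel(n_components).fit(X, y)


def _resolve(matrix) -> tuple[np.ndarray, DescriptorMatrix | None]:
    if isinstance(matrix, DescriptorMatrix):
        return matrix.X, matrix
    return np.asarray(matrix, dtype=float), None


def loo_q2(
    matrix,
    y: np.ndarray,
    max_components: int,
    preprocess: PreprocessSpec | None = None,
) -> dict:
    """Leave-one-out cross-validation over 1..max_components latent variables.

    When ``matrix`` is a :class:`DescriptorMatrix` and a ``preprocess`` spec
    is given, column filtering and block scaling are refit inside every fold
    on the n−1 training rows.  Returns per-N q² and SEP plus the optimal N
    (max q², ties to fewer components, capped at ⌊n/3⌋).
    """
    X_raw, dmat = _resolve(matrix)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOO needs at least 3 rows")
    if max_components >= n - 1:
        raise ValueError("max_components must be < n - 1")
    if max_components < 1:
        raise ValueError("max_components must be >= 1")

    y_mean = y.mean()  # full training-set mean (fixed across folds)
    ss_total = float(np.sum((y - y_mean) ** 2))
    preds = np.empty((max_components, n))
    for i in range(n):
        train = np.r_[0:i, i + 1 : n]
        if dmat is not None and preprocess is not None:
            prep = Preprocessor(preprocess).fit(dmat.select_rows(train))
            Xtr = prep.transform(X_raw[train])
            Xte = prep.transform(X_raw[i : i + 1])
        else:
            Xtr, Xte = X_raw[train], X_raw[i : i + 1]
        for N in range(1, max_components + 1):
            model = PLSModel(N).fit(Xtr, y[train])
            preds[N - 1, i] = model.predict(Xte)[0]

    press = np.sum((y[None, :] - preds) ** 2, axis=1)
    q2 = 1.0 - press / ss_total
    dof = n - np.arange(1, max_components + 1) - 1
    sep = np.sqrt(np.where(dof > 0, press / np.maximum(dof, 1), np.nan))
    cap = max(n // 3, 1)
    candidates = np.arange(1, max_components + 1)
    allowed = candidates <= cap
    if not allowed.any():
        allowed = candidates == 1
    q2_allowed = np.where(allowed, q2, -np.inf)
    optimal = int(candidates[np.argmax(q2_allowed)])  # argmax keeps the smallest on ties
    return {
        "q2": q2,
        "sep": sep,
        "press": press,
        "n_components": candidates,
        "optimal_n": optimal,
        "loo_predictions": preds,
    }


@dataclass
class PLSModelSummary:
    """Fitted model plus the standard internal statistics."""

    name: str
    n_components: int
    q2: float
    sep: float
    see: float
    r2_ncv: float
    f_stat: float
    field_contributions: dict[str, float]
    coefficients: np.ndarray  # original (unscaled) column space, retained columns
    intercept: float
    training_mean: float
    retained_field_types: np.ndarray
    retained_grid_indices: np.ndarray
    retained_column_sd: np.ndarray  # training sd per retained column, native units
    preprocessor: Preprocessor = field(repr=False, default=None)
    r2_test: float | None = None

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Predict activities for rows in the original descriptor space."""
        X_raw = np.asarray(X_raw, dtype=float)
        if X_raw.shape[1] == len(self.coefficients):
            return X_raw @ self.coefficients + self.intercept
        if self.preprocessor is not None and X_raw.shape[1] == len(self.preprocessor.keep_):
            Xf = X_raw[:, self.preprocessor.keep_]
            return Xf @ self.coefficients + self.intercept
        raise ValueError(
            f"descriptor row length {X_raw.shape[1]} matches neither the retained "
            f"columns ({len(self.coefficients)}) nor the pre-filter columns"
        )


def summarize_model(
    matrix,
    y: np.ndarray,
    n_components: int,
    preprocess: PreprocessSpec | None = None,
    q2: float | None = None,
    sep: float | None = None,
    name: str = "model",
) -> PLSModelSummary:
    """Fit on the full training set and compute the internal statistics."""
    X_raw, dmat = _resolve(matrix)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n - n_components - 1 <= 0:
        raise ValueError("too many components for the number of training rows")

    if dmat is not None:
        prep = Preprocessor(preprocess or PreprocessSpec()).fit(dmat)
        X = prep.transform(X_raw)
        field_types = prep.field_types_
        grid_indices = prep.grid_indices_
        scale = prep.scale_
    else:
        prep = None
        X = X_raw
        field_types = np.full(X.shape[1], "all", dtype=object)
        grid_indices = np.arange(X.shape[1])
        scale = np.ones(X.shape[1])

    model = PLSModel(n_components).fit(X, y)
    fitted = model.predict(X)
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2_ncv = 1.0 - rss / tss
    see = float(np.sqrt(rss / (n - n_components - 1)))
    denom = (1.0 - r2_ncv) / (n - n_components - 1)
    f_stat = float((r2_ncv / n_components) / denom) if denom > 0 else float("inf")

    # contributions: sum |coef|*sd per block on the scaled columns (scale-invariant)
    col_sd_scaled = np.std(X, axis=0, ddof=1)
    contrib_raw = {}
    for ft in dict.fromkeys(field_types):
        cols = field_types == ft
        contrib_raw[str(ft)] = float(np.sum(np.abs(model.coef_[cols]) * col_sd_scaled[cols]))
    total = sum(contrib_raw.values())
    contributions = {k: (v / total if total > 0 else 0.0) for k, v in contrib_raw.items()}

    # coefficients back in native column units (undo block scaling)
    coef_native = model.coef_ * scale

    return PLSModelSummary(
        name=name,
        n_components=n_components,
        q2=float("nan") if q2 is None else float(q2),
        sep=float("nan") if sep is None else float(sep),
        see=see,
        r2_ncv=r2_ncv,
        f_stat=f_stat,
        field_contributions=contributions,
        coefficients=coef_native,
        intercept=model.intercept_,
        training_mean=float(y.mean()),
        retained_field_types=field_types,
        retained_grid_indices=grid_indices,
        retained_column_sd=col_sd_scaled / scale,
        preprocessor=prep,
    )
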