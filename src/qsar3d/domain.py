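"""Applicability domain by the standardization approach.

Each descriptor i of a query compound k is standardized against the
training set: ``S_ik = |x_ik − mean_i| / sd_i`` (sample sd, training
columns with zero sd are dropped).  The decision rule:

* if max_i S_ik ≤ 3 the compound is inside the domain;
* if min_i S_ik ≥ 3 it is outside;
* otherwise compute ``S_new = S̄_k + 1.28·σ(S_k)`` and call the compound
  inside iff S_new ≤ 3.

The 1.28 factor places the threshold at the upper 90th percentile of the
compound's standardized-descriptor distribution under a normal assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ADRecord", "standardize_descriptors", "classify_ad", "ad_report"]

_THRESHOLD = 3.0
_PERCENTILE_FACTOR = 1.28


@dataclass
class ADRecord:
    compound_id: str
    s_max: float
    s_min: float
    s_new: float | None
    status: str  # "inside" | "outside"


def standardize_descriptors(
    X_train: np.ndarray, X_query: np.ndarray, ddof: int = 1
) -> np.ndarray:
    """|x − mean| / sd per descriptor, statistics from the training rows.

    Zero-variance training columns are dropped (with a warning) from both
    matrices before standardization.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_query = np.asarray(X_query, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("X_train needs at least 2 rows")
    if X_query.ndim != 2 or X_query.shape[1] != X_train.shape[1]:
        raise ValueError("X_query columns must match X_train")
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance descriptor(s) "
            "before standardization",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("all descriptors have zero training variance")
    return np.abs(X_query[:, keep] - mean[keep]) / sd[keep]


def classify_ad(s_row: np.ndarray, compound_id: str = "", ddof: int = 1) -> ADRecord:
    """Inside/outside verdict for one compound's standardized descriptors."""
    s = np.asarray(s_row, dtype=float)
    if s.ndim != 1 or len(s) == 0:
        raise ValueError("need a non-empty vector of standardized descriptors")
    s_max = float(s.max())
    s_min = float(s.min())
    if s_max <= _THRESHOLD:
        return ADRecord(compound_id, s_max, s_min, None, "inside")
    if s_min >= _THRESHOLD:
        return ADRecord(compound_id, s_max, s_min, None, "outside")
    sd = float(np.std(s, ddof=ddof)) if len(s) > ddof else 0.0
    s_new = float(s.mean()) + _PERCENTILE_FACTOR * sd
    status = "inside" if s_new <= _THRESHOLD else "outside"
    return ADRecord(compound_id, s_max, s_min, s_new, status)


def ad_report(
    X_train: np.ndarray,
    X_query: np.ndarray,
    ids: list[str] | None = None,
    ddof: int = 1,
) -> tuple[list[ADRecord], pd.DataFrame]:
    """Classify every query row; returns records and a CSV-ready table."""
    S = standardize_descriptors(X_train, X_query, ddof=ddof)
    if ids is None:
        ids = [str(i + 1) for i in range(S.shape[0])]
    records = [classify_ad(S[i], compound_id=ids[i], ddof=ddof) for i in range(S.shape[0])]
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "s_max": [r.s_max for r in records],
            "s_min": [r.s_min for r in records],
            "s_new": [r.s_new for r in records],
            "status": [r.status for r in records],
        }
    )
    return records, df
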