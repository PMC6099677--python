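"""External (test-set) validation: Golbraikh–Tropsha battery and rm² metrics.

For experimental activities x and predictions y on the test set the battery
computes the squared Pearson correlation r², the through-origin regressions
in both orientations — slope k and determination coefficient r0² for
predicted-on-experimental, and k′, r0′² for experimental-on-predicted —
and checks the classical conditions for a predictive model:

* q² > 0.5 (internal, supplied by the caller),
* r² > 0.6,
* (r² − r0²)/r² < 0.1 or (r² − r0′²)/r² < 0.1,
* 0.85 ≤ k ≤ 1.15 or 0.85 ≤ k′ ≤ 1.15,
* |r0² − r0′²| < 0.3.

Roy's rm² metric is reported in both circulating variants:
``abs``:  r²·(1 − |r² − r0²|)   and   ``sqrt``:  r²·(1 − √(r² − r0²)).
The sqrt form is the default.  Residuals are experimental − predicted;
compounds whose |residual| exceeds a threshold (default 0.4 log units) are
flagged as outliers, and all metrics are reported both with and without
the flagged compounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ExternalValidationReport",
    "predict",
    "through_origin_stats",
    "external_metrics",
    "rm2",
    "flag_outliers",
]


def predict(model, X_new: np.ndarray) -> np.ndarray:
    """Score new descriptor rows with a fitted model summary."""
    return model.predict(X_new)


def through_origin_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and determination coefficient of y = k·x through the origin.

    k = Σxy/Σx²;  r0² = 1 − Σ(y − kx)²/Σ(y − ȳ)².
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of at least 3 points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("through-origin slope undefined: sum of squares of x is zero")
    syy_about_mean = float(np.sum((y - y.mean()) ** 2))
    if syy_about_mean == 0:
        raise ValueError("y has zero variance")
    k = float(np.sum(x * y) / sxx)
    r0_sq = 1.0 - float(np.sum((y - k * x) ** 2)) / syy_about_mean
    return k, r0_sq


def rm2(r2: float, r0_sq: float, variant: str = "sqrt") -> float:
    """Roy's rm² metric.  abs: r²(1−|r²−r0²|); sqrt: r²(1−√(r²−r0²))."""
    if variant == "abs":
        return r2 * (1.0 - abs(r2 - r0_sq))
    if variant == "sqrt":
        if r0_sq > r2:
            raise ValueError("sqrt variant requires r0_sq <= r2")
        return r2 * (1.0 - np.sqrt(r2 - r0_sq))
    raise ValueError(f"unknown rm2 variant {variant!r}")


def flag_outliers(residuals: Mapping[str, float], threshold: float = 0.4) -> list[str]:
    """Ids whose |experimental − predicted| exceeds ``threshold`` log units."""
    if threshold <= 0:
        raise ValueError("outlier threshold must be positive")
    return [cid for cid, res in residuals.items() if abs(res) > threshold]


@dataclass
class ExternalValidationReport:
    r2: float
    r0_sq: float  # predicted on experimental, through origin
    r0_prime_sq: float  # experimental on predicted, through origin
    k: float
    k_prime: float
    conditions: dict[str, bool]
    rm_sq_abs: float
    rm_sq_sqrt: float | None  # None when r0² > r² (sqrt undefined)
    residuals: dict[str, float]
    outlier_ids: list[str]
    q2: float | None = None
    r2_press: float = float("nan")  # 1 − PRESS/SD predictive r², reported separately

    def condition_table(self):
        """Long-form condition report (id, parameter, threshold, value, verdict)."""
        import pandas as pd

        rows = [
            ("1", "q2", "> 0.5", self.q2, self.conditions.get("q2_gt_0.5")),
            ("2", "r2", "> 0.6", self.r2, self.conditions["r2_gt_0.6"]),
            ("3a", "r0_sq", "close to r2", self.r0_sq, None),
            ("3b", "r0_prime_sq", "close to r2", self.r0_prime_sq, None),
            ("4a", "k", "0.85..1.15", self.k, 0.85 <= self.k <= 1.15),
            ("4b", "k_prime", "0.85..1.15", self.k_prime, 0.85 <= self.k_prime <= 1.15),
            ("5a", "(r2-r0_sq)/r2", "< 0.1", (self.r2 - self.r0_sq) / self.r2, None),
            ("5b", "(r2-r0_prime_sq)/r2", "< 0.1", (self.r2 - self.r0_prime_sq) / self.r2, None),
            ("6", "|r0_sq-r0_prime_sq|", "< 0.3", abs(self.r0_sq - self.r0_prime_sq),
             self.conditions["r0_diff_lt_0.3"]),
            ("7", "rm2(sqrt)", "> 0.5", self.rm_sq_sqrt,
             None if self.rm_sq_sqrt is None else self.rm_sq_sqrt > 0.5),
        ]
        return pd.DataFrame(rows, columns=["condition", "parameter", "threshold", "value", "verdict"])


def external_metrics(
    y_exp: np.ndarray,
    y_pred: np.ndarray,
    ids: Sequence[str] | None = None,
    q2: float | None = None,
    outlier_threshold: float = 0.4,
) -> ExternalValidationReport:
    """Full test-set validation battery on experimental vs predicted activities."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape or y_exp.ndim != 1 or len(y_exp) < 3:
        raise ValueError("need two equal-length vectors of at least 3 points")
    if np.std(y_exp) == 0 or np.std(y_pred) == 0:
        raise ValueError("zero variance in experimental or predicted activities")
    if ids is None:
        ids = [str(i + 1) for i in range(len(y_exp))]

    r2 = float(np.corrcoef(y_exp, y_pred)[0, 1] ** 2)
    k, r0_sq = through_origin_stats(y_exp, y_pred)
    k_prime, r0_prime_sq = through_origin_stats(y_pred, y_exp)

    conditions = {
        "q2_gt_0.5": None if q2 is None else bool(q2 > 0.5),
        "r2_gt_0.6": bool(r2 > 0.6),
        "origin_ratio_lt_0.1": bool(
            (r2 - r0_sq) / r2 < 0.1 or (r2 - r0_prime_sq) / r2 < 0.1
        ),
        "slope_in_band": bool(0.85 <= k <= 1.15 or 0.85 <= k_prime <= 1.15),
        "r0_diff_lt_0.3": bool(abs(r0_sq - r0_prime_sq) < 0.3),
    }

    rm_abs = rm2(r2, r0_sq, "abs")
    rm_sqrt = rm2(r2, r0_sq, "sqrt") if r0_sq <= r2 else None

    residuals = {cid: float(e - p) for cid, e, p in zip(ids, y_exp, y_pred)}
    outliers = flag_outliers(residuals, outlier_threshold)

    press = float(np.sum((y_exp - y_pred) ** 2))
    sd = float(np.sum((y_exp - y_exp.mean()) ** 2))
    r2_press = 1.0 - press / sd

    return ExternalValidationReport(
        r2=r2,
        r0_sq=r0_sq,
        r0_prime_sq=r0_prime_sq,
        k=k,
        k_prime=k_prime,
        conditions=conditions,
        rm_sq_abs=rm_abs,
        rm_sq_sqrt=rm_sqrt,
        residuals=residuals,
        outlier_ids=outliers,
        q2=q2,
        r2_press=r2_press,
    )
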