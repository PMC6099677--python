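"""Field-combination enumeration and model ranking.

Candidate models are built from non-empty subsets of the available fields
(CoMFA: steric/electrostatic, 3 subsets; CoMSIA: all five properties, 31
subsets).  A model is eligible only if its internal q² exceeds 0.5;
eligible models are ranked by test-set r² (descending), ties broken by q².
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .fields import (
    COMSIA_FIELDS,
    DescriptorMatrix,
    assemble_descriptors,
    comfa_fields,
    comsia_fields,
)
from .pls import PLSModelSummary, PreprocessSpec, loo_q2, summarize_model

__all__ = ["FieldCombination", "enumerate_models", "rank_models", "fit_combination",
           "TABLE1_PRESET"]

FIELD_ORDER = "SEHDA"
_FIELD_CODE = {
    "S": "steric",
    "E": "electrostatic",
    "H": "hydrophobic",
    "D": "donor",
    "A": "acceptor",
}


@dataclass(frozen=True)
class FieldCombination:
    method: str  # "CoMFA" | "CoMSIA"
    included_fields: tuple[str, ...]  # subset of S,E,H,D,A in canonical order

    def __post_init__(self) -> None:
        if self.method not in ("CoMFA", "CoMSIA"):
            raise ValueError(f"unknown method {self.method!r}")
        if not self.included_fields:
            raise ValueError("field combination must be non-empty")
        allowed = "SE" if self.method == "CoMFA" else FIELD_ORDER
        if any(f not in allowed for f in self.included_fields):
            raise ValueError(f"fields {self.included_fields} invalid for {self.method}")

    @property
    def name(self) -> str:
        letters = "".join(self.included_fields)
        if self.method == "CoMSIA" and len(self.included_fields) == 5:
            letters = "ALL"
        return f"{self.method}-{letters}"

    def field_types(self) -> list[str]:
        prefix = self.method.lower()
        return [f"{prefix}_{_FIELD_CODE[f]}" for f in self.included_fields]


#: the named field combinations reported in the source study's summary table
TABLE1_PRESET = [
    FieldCombination("CoMFA", ("S", "E")),
    FieldCombination("CoMSIA", ("S", "E")),
    FieldCombination("CoMSIA", ("S", "E", "H", "A")),
    FieldCombination("CoMSIA", ("S", "E", "A")),
    FieldCombination("CoMSIA", ("S", "E", "D", "A")),
    FieldCombination("CoMSIA", ("S", "D")),
    FieldCombination("CoMSIA", ("S", "H", "D")),
    FieldCombination("CoMSIA", ("E", "H", "A")),
    FieldCombination("CoMSIA", ("E", "H", "D", "A")),
    FieldCombination("CoMSIA", ("S", "E", "H", "D", "A")),
]


def enumerate_models(
    method: str, fields_universe: Sequence[str] | None = None
) -> list[FieldCombination]:
    """All non-empty field subsets in deterministic (size, canonical) order."""
    if fields_universe is None:
        fields_universe = "SE" if method == "CoMFA" else FIELD_ORDER
    universe = [f for f in FIELD_ORDER if f in fields_universe]
    if not universe:
        raise ValueError("empty field universe")
    combos = []
    for size in range(1, len(universe) + 1):
        for subset in combinations(universe, size):
            combos.append(FieldCombination(method, subset))
    return combos


def rank_models(
    summaries: Sequence[PLSModelSummary], q2_threshold: float = 0.5
) -> list[tuple[PLSModelSummary, bool]]:
    """Sort models: eligible (q² > threshold) first by test r² desc, ties by q².

    Returns (summary, eligible) pairs; ineligible models trail in the same
    ordering.  The sort is stable under input permutation because the keys
    are total.
    """
    if not summaries:
        raise ValueError("rank_models needs at least one summary")

    def key(s: PLSModelSummary):
        eligible = s.q2 > q2_threshold
        r2t = s.r2_test if s.r2_test is not None else float("-inf")
        return (not eligible, -r2t, -s.q2, s.name)

    ordered = sorted(summaries, key=key)
    return [(s, s.q2 > q2_threshold) for s in ordered]


def fit_combination(
    combo: FieldCombination,
    dataset,
    grid,
    preprocess: PreprocessSpec | None = None,
    max_components: int | None = None,
    cutoff: float = 30.0,
    alpha: float = 0.3,
) -> PLSModelSummary:
    """Compute fields for one combination, fit with LOO, and score the test set."""
    from .validation import external_metrics

    train = dataset.subset("train")
    test = dataset.subset("test")
    if combo.method == "CoMFA":
        blocks = {b.field_type: b for b in comfa_fields(train + test, grid, cutoff=cutoff)}
    else:
        blocks = {b.field_type: b for b in comsia_fields(train + test, grid, alpha=alpha)}
    wanted = combo.field_types()
    all_ids = [m.id for m in train + test]
    matrix = assemble_descriptors([blocks[ft] for ft in wanted], all_ids)
    n_train = len(train)
    train_matrix = matrix.select_rows(range(n_train))
    y_train = dataset.y("train")
    y_test = dataset.y("test")

    n = len(y_train)
    if max_components is None:
        max_components = min(max(n // 3, 1), n - 2)
    cv = loo_q2(train_matrix, y_train, max_components=max_components, preprocess=preprocess)
    N = cv["optimal_n"]
    summary = summarize_model(
        train_matrix,
        y_train,
        N,
        preprocess=preprocess,
        q2=float(cv["q2"][N - 1]),
        sep=float(cv["sep"][N - 1]),
        name=combo.name,
    )
    if len(test) >= 3:
        X_test = matrix.X[n_train:]
        y_pred = summary.predict(X_test)
        report = external_metrics(y_test, y_pred, ids=[m.id for m in test], q2=summary.q2)
        summary.r2_test = report.r2
    return summary
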