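#!/usr/bin/env python
"""Applicability-domain screening of the synthetic test set.

Standardizes every retained descriptor of each test compound against the
training-set mean and sd and applies the three-branch decision rule
(s_max ≤ 3 → inside; s_min ≥ 3 → outside; otherwise S_new = S̄ + 1.28σ ≤ 3).
Writes results/applicability_domain.csv.
"""

from pathlib import Path

from qsar3d.domain import ad_report
from qsar3d.fields import assemble_descriptors, build_grid, comfa_fields
from qsar3d.pls import Preprocessor, PreprocessSpec
from qsar3d.synthetic import GeneratorSpec, generate_dataset

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dataset, _ = generate_dataset(GeneratorSpec(noise_sd=0.1))
    train, test = dataset.subset("train"), dataset.subset("test")
    grid = build_grid(dataset.molecules)
    matrix = assemble_descriptors(
        comfa_fields(train + test, grid), [m.id for m in train + test]
    )
    prep = Preprocessor(PreprocessSpec(2.0, "comfa_std")).fit(
        matrix.select_rows(range(len(train)))
    )
    X_train = prep.transform(matrix.X[: len(train)])
    X_test = prep.transform(matrix.X[len(train):])

    records, df = ad_report(X_train, X_test, ids=[m.id for m in test])
    print(df.to_string(index=False))
    outside = [r.compound_id for r in records if r.status == "outside"]
    print(f"\n{len(records) - len(outside)}/{len(records)} test compounds inside the domain"
          + (f"; outside: {outside}" if outside else ""))
    df.to_csv(OUT / "applicability_domain.csv", index=False)


if __name__ == "__main__":
    main()
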