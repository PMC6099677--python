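#!/usr/bin/env python
"""Generate the default synthetic aligned-molecule study and write it to disk.

Produces results/synthetic/: molecules.sdf, activities.csv, manifest.csv and
the planted ground truth (truth.json).  The defaults emulate the study
shape: 41 congeneric pseudo-molecules, 29/12 train/test split, activities
spanning ~3.5 pEC50 log units with Gaussian noise sd 0.1.
"""

import json
from pathlib import Path

import pandas as pd

from qsar3d.structures import write_manifest
from qsar3d.synthetic import GeneratorSpec, generate_dataset, write_structures

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = GeneratorSpec(noise_sd=0.1)
    dataset, truth = generate_dataset(spec)

    write_structures(dataset.molecules, OUT / "molecules.sdf", fmt="sdf")
    pd.DataFrame(
        {
            "id": dataset.ids,
            "pec50": [dataset.activities[i].pec50 for i in dataset.ids],
            "role": [dataset.roles[i] for i in dataset.ids],
        }
    ).to_csv(OUT / "activities.csv", index=False)
    write_manifest(dataset, OUT / "manifest.csv")
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "true_weights": {f"site{s}:{p}": w for (s, p), w in truth.true_weights.items()},
                "site_positions": [list(p) for p in truth.site_positions],
                "noiseless_activity": truth.noiseless_activity,
            },
            indent=2,
        )
    )

    y = dataset.y()
    print(f"wrote {len(dataset.molecules)} molecules to {OUT}")
    print(f"activity span: {y.min():.2f} .. {y.max():.2f} pEC50 "
          f"({y.max() - y.min():.2f} log units)")
    print(f"train/test: {len(dataset.subset('train'))}/{len(dataset.subset('test'))}")


if __name__ == "__main__":
    main()
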