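"""End-to-end pipeline: fields → fit → validate → y-randomize → AD → contours.

Used by the command-line interface and the analysis drivers; every stage is
a thin call into the corresponding module, and the resolved configuration
is echoed into the run log for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import export_volumetric, stdev_coeff_field, threshold_levels
from .domain import ad_report
from .fields import assemble_descriptors, build_grid, comfa_fields, comsia_fields
from .pls import PreprocessSpec, loo_q2, summarize_model
from .selection import FieldCombination
from .structures import AlignedDataset
from .validation import external_metrics
from .yrand import y_randomize

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paper-default settings for one modelling run."""

    method: str = "CoMSIA"  # or "CoMFA"
    fields: str = "SEHDA"  # subset letters; CoMFA uses "SE"
    spacing: float = 2.0  # Å
    padding: float = 4.0  # Å
    cutoff: float = 30.0  # kcal/mol
    alpha: float = 0.3
    column_filter: float = 2.0
    scaling: str = "comfa_std"
    outlier_threshold: float = 0.4  # pEC50 log units
    rm2_variant: str = "sqrt"
    n_yrand: int = 10
    seed: int = 0
    max_components: int | None = None

    def preprocess(self) -> PreprocessSpec:
        return PreprocessSpec(column_filter_threshold=self.column_filter, scaling=self.scaling)


def run_pipeline(
    dataset: AlignedDataset,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full modelling workflow on an aligned dataset.

    Returns a bundle with the grid, descriptor matrix, model summary,
    external validation report, Y-randomization results, AD records and
    contour fields.  When ``out_dir`` is given, CSV reports, volumetric
    files and the resolved-config log are written there.
    """
    config = config or RunConfig()
    combo = FieldCombination(config.method, tuple(config.fields))

    train = dataset.subset("train")
    test = dataset.subset("test")
    all_mols = train + test
    grid = build_grid(all_mols, spacing=config.spacing, padding=config.padding)
    if combo.method == "CoMFA":
        blocks = {b.field_type: b for b in comfa_fields(all_mols, grid, cutoff=config.cutoff)}
    else:
        blocks = {b.field_type: b for b in comsia_fields(all_mols, grid, alpha=config.alpha)}
    matrix = assemble_descriptors(
        [blocks[ft] for ft in combo.field_types()], [m.id for m in all_mols]
    )
    n_train = len(train)
    train_matrix = matrix.select_rows(range(n_train))
    y_train = dataset.y("train")

    max_n = config.max_components or min(max(len(train) // 3, 1), len(train) - 2)
    prep = config.preprocess()
    cv = loo_q2(train_matrix, y_train, max_components=max_n, preprocess=prep)
    N = cv["optimal_n"]
    summary = summarize_model(
        train_matrix, y_train, N, preprocess=prep,
        q2=float(cv["q2"][N - 1]), sep=float(cv["sep"][N - 1]), name=combo.name,
    )

    report = None
    if len(test) >= 3:
        y_pred = summary.predict(matrix.X[n_train:])
        report = external_metrics(
            dataset.y("test"), y_pred, ids=[m.id for m in test],
            q2=summary.q2, outlier_threshold=config.outlier_threshold,
        )
        summary.r2_test = report.r2

    yrand_results, yrand_verdict = y_randomize(
        train_matrix, y_train, n_components=N, n_iterations=config.n_yrand,
        seed=config.seed, preprocess=prep,
    )

    prep_fitted = summary.preprocessor
    X_train_p = prep_fitted.transform(train_matrix.X)
    X_test_p = prep_fitted.transform(matrix.X[n_train:]) if test else X_train_p[:0]
    ad_records, ad_df = ad_report(
        X_train_p, X_test_p if len(test) else X_train_p,
        ids=[m.id for m in (test if test else train)],
    )

    contour_fields = {}
    for ft in combo.field_types():
        cf = stdev_coeff_field(summary, grid.n_points, ft)
        if np.any(cf.values != 0):
            threshold_levels(cf)
        contour_fields[ft] = cf

    bundle = {
        "config": config,
        "grid": grid,
        "matrix": matrix,
        "cv": cv,
        "summary": summary,
        "external": report,
        "yrand": (yrand_results, yrand_verdict),
        "ad": ad_records,
        "contours": contour_fields,
    }
    if out_dir is not None:
        _write_reports(bundle, ad_df, Path(out_dir))
    return bundle


def _write_reports(bundle: dict, ad_df: pd.DataFrame, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config = bundle["config"]
    summary = bundle["summary"]
    (out_dir / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")

    stats = {
        "model": summary.name, "q2": summary.q2, "n_components": summary.n_components,
        "sep": summary.sep, "see": summary.see, "r2_ncv": summary.r2_ncv,
        "f": summary.f_stat, "r2_test": summary.r2_test,
    }
    stats.update({f"contrib_{k}": v for k, v in summary.field_contributions.items()})
    pd.DataFrame([stats]).to_csv(out_dir / "model_statistics.csv", index=False)

    if bundle["external"] is not None:
        bundle["external"].condition_table().to_csv(out_dir / "external_validation.csv", index=False)

    results, verdict = bundle["yrand"]
    pd.DataFrame(
        {"iteration": [r.iteration for r in results], "q2": [r.q2 for r in results],
         "r2_ncv": [r.r2_ncv for r in results]}
    ).to_csv(out_dir / "y_randomization.csv", index=False)

    ad_df.to_csv(out_dir / "applicability_domain.csv", index=False)

    for ft, cf in bundle["contours"].items():
        export_volumetric(cf, bundle["grid"], out_dir / f"{summary.name}_{ft}.dx", fmt="dx")
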