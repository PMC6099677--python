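"""Shared fixtures: paper-table data and the default synthetic study."""

import numpy as np
import pytest

from qsar3d.synthetic import GeneratorSpec, generate_dataset, load_paper_fixtures
from qsar3d.workflow import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def tables():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def table3(tables):
    return tables["table3"]


@pytest.fixture(scope="session")
def synthetic_study():
    """Default-condition synthetic dataset (41 molecules, noise sd 0.1)."""
    return generate_dataset(GeneratorSpec(noise_sd=0.1))


@pytest.fixture(scope="session")
def comfa_bundle(synthetic_study):
    """Full CoMFA-SE pipeline run on the default synthetic dataset."""
    dataset, _ = synthetic_study
    return run_pipeline(
        dataset, RunConfig(method="CoMFA", fields="SE", column_filter=2.0, seed=1, n_yrand=1)
    )


@pytest.fixture(scope="session")
def comsia_bundle(synthetic_study):
    """Full CoMSIA-ALL pipeline run (similarity fields, no column filter)."""
    dataset, _ = synthetic_study
    return run_pipeline(
        dataset,
        RunConfig(method="CoMSIA", fields="SEHDA", column_filter=0.0, seed=1, n_yrand=1),
    )


def table3_test_vectors(table3, model: str, exclude_outliers: bool = True):
    """Experimental/predicted vectors for one model's test set from the fixture."""
    sub = table3[table3.is_test == 1]
    if exclude_outliers:
        sub = sub[sub[f"{model}_outlier"] == 0]
    return (
        sub["experimental_pec50"].to_numpy(),
        sub[f"{model}_pred"].to_numpy(),
        sub["id"].astype(str).tolist(),
    )
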