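from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coexfeat import default_spec, generate_expression
from coexfeat.containers import ExpressionMatrix
from coexfeat.preprocess import correct_batch

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared by read-only tests."""
    return generate_expression(default_spec(seed=11))


@pytest.fixture(scope="session")
def corrected_study(study):
    matrix, truth = study
    return correct_batch(matrix), truth


def toy_matrix(values, phenotype=None, batch=None) -> ExpressionMatrix:
    """Small ExpressionMatrix from a 2-D array for hand-built examples."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    cols = [f"s{j}" for j in range(n_samples)]
    if phenotype is None:
        phenotype = [0] * (n_samples // 2) + [1] * (n_samples - n_samples // 2)
    if batch is None:
        batch = ["B1"] * n_samples
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)], columns=cols),
        pd.Series(batch, index=cols),
        pd.Series(phenotype, index=cols),
    )
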