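import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from timeprofiler.core import ExpressionMatrix, ZExpressionMatrix, zscore
from timeprofiler.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-sample cohort with planted truth, shared across tests."""
    return generate_cohort(CohortConfig(n_samples=300, seed=7))


@pytest.fixture(scope="session")
def small_cohort_z(small_cohort):
    return zscore(small_cohort.expression)


@pytest.fixture()
def toy_z():
    """A hand-specified z-matrix for rule-boundary tests.

    Genes are the eight immune markers; values are already standardized by
    construction (passed straight into a ZExpressionMatrix).
    """

    def make(values: dict[str, list[float]], genes: list[str]) -> ZExpressionMatrix:
        # keys of ``values`` are sample ids, each mapping to per-gene vectors
        return ZExpressionMatrix(pd.DataFrame(values, index=genes))

    return make


def random_zmatrix(n_genes: int, n_samples: int, seed: int) -> ZExpressionMatrix:
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    return ZExpressionMatrix(
        pd.DataFrame(rng.standard_normal((n_genes, n_samples)),
                     index=genes, columns=samples)
    )
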