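import numpy as np
import pandas as pd
import pytest

from gliomune.synthetic import CohortConfig, make_cohort


@pytest.fixture(scope="session")
def expression_cohort():
    """Expression-only cohort, large enough for scoring/clustering checks."""
    return make_cohort(CohortConfig(n_samples=100, with_images=False, seed=7))


@pytest.fixture(scope="session")
def imaging_cohort():
    """Small imaged cohort for radiomics/QC plumbing checks."""
    return make_cohort(CohortConfig(n_samples=6, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_expression():
    """A hand-sized expression matrix with unambiguous ranks."""
    genes = [f"g{i}" for i in range(6)]
    return pd.DataFrame(
        {
            "sampleA": [10.0, 9.0, 8.0, 3.0, 2.0, 1.0],
            "sampleB": [1.0, 2.0, 3.0, 8.0, 9.0, 10.0],
        },
        index=genes,
    )
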