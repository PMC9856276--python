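import numpy as np
import pandas as pd
import pytest

from protpanel import ProteinMatrix, SampleMetadata, small_config
from protpanel.synth import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 proteins of raw RFU."""
    values = pd.DataFrame(
        [[10.0, 100.0], [20.0, 200.0], [40.0, 400.0]],
        index=["S1", "S2", "S3"],
        columns=["P1", "P2"],
    )
    return ProteinMatrix(values, transform_state="raw")


@pytest.fixture
def tiny_metadata():
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["S1", "S2", "S3"],
        "status": ["case", "case", "control"],
        "age": [70.0, 65.0, 60.0],
        "sex": ["male", "female", "male"],
        "moca": [25, 28, 30],
        "updrs3": [30, 12, 1],
    }))


@pytest.fixture(scope="session")
def small_cohort():
    """200-sample serum cohort, 100 proteins, 3 planted case proteins."""
    cfg = small_config(
        n_samples=200, case_fraction=0.5, n_proteins=100, seed=7,
        informative_proteins=(("P00010", 0.8), ("P00020", 0.8), ("P00030", 0.8)),
    )
    return generate_cohort(cfg, "serum")
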