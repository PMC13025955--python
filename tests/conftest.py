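import numpy as np
import pandas as pd
import pytest

from medhg import cohort_features as cf
from medhg import hetgraph as hg
from medhg.synthetic_ehr import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A ~650-encounter synthetic cohort with default planted effects."""
    cfg = SyntheticConfig(n_patients=500, seed=7)
    enc, asg, trf = generate_cohort(cfg)
    return cfg, enc, asg, trf


@pytest.fixture(scope="session")
def prepared(small_cohort):
    """Splits, labels and feature matrix for the small cohort."""
    _, enc, asg, trf = small_cohort
    splits = cf.split_indices(enc, seed=7)
    labels = cf.derive_outcomes(enc, reference_rows=splits.train)
    matrix, fz = cf.build_feature_matrix(enc, splits.train)
    return splits, labels, matrix, fz


@pytest.fixture(scope="session")
def small_graph(small_cohort, prepared):
    _, enc, asg, trf = small_cohort
    _, _, matrix, _ = prepared
    return hg.build_heterograph(enc, asg, trf, matrix)


@pytest.fixture
def toy_tables():
    """Two encounters, hand-written assignments and transfers."""
    enc = pd.DataFrame({
        "encounter_id": ["e1", "e2"],
        "patient_id": ["p1", "p2"],
        "postop_los": [3.0, 9.0],
        "death_offset": [np.nan, 12.0],
    })
    asg = pd.DataFrame({
        "encounter_id": ["e1", "e1", "e2"],
        "provider_id": ["s1", "n1", "s1"],
        "role": ["surgical_team", "nurse", "surgical_team"],
    })
    trf = pd.DataFrame({
        "encounter_id": ["e1", "e1", "e1"],
        "unit_type": ["acute", "intensive", "acute"],
        "sequence_index": [0, 1, 2],
        "duration": [10.0, 24.0, 5.0],
    })
    return enc, asg, trf
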