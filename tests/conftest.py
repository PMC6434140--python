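import numpy as np
import pytest

from ckdtraj.cohort import CohortConfig, generate_cohort
from ckdtraj.io import records_to_frame
from ckdtraj.staging import stage_cohort

#: Baseline 4x4 stage-cell subject counts of a reference checkup
#: population (rows G1..G3b, columns (-),(+/-),(+),(2+)); total 7465.
BASELINE_GRID = [
    [1375, 53, 25, 10],
    [5061, 355, 129, 36],
    [322, 34, 18, 16],
    [17, 3, 2, 9],
]


@pytest.fixture(scope="session")
def default_cohort_df():
    """Mid-sized drift cohort shared across read-only tests."""
    return records_to_frame(generate_cohort(
        CohortConfig(n_subjects=2000, seed=1)))


@pytest.fixture(scope="session")
def default_staged(default_cohort_df):
    return stage_cohort(default_cohort_df)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
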