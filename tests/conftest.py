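import numpy as np
import pytest

from predecline.change import AVERAGED_CLUSTER, roi_change_table
from predecline.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 120-subject cohort, reused across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def cluster_change(default_cohort):
    """Averaged-cluster change values aligned with the cohort rows."""
    table = roi_change_table(default_cohort)
    q = (
        table[table.roi == AVERAGED_CLUSTER]
        .set_index("subject_id")["q_value"]
        .loc[default_cohort["subject_id"]]
        .to_numpy()
    )
    return q


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
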