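import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tdcsgraph.connectome import ThresholdedGraph
from tdcsgraph.synthetic_data import CohortConfig, SubjectRecord, make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_weighted_graph(n, density, rng, as_graph=True):
    """Random symmetric positive-weight matrix with ~density edge fraction."""
    upper = np.triu((rng.random((n, n)) < density) * rng.random((n, n)), 1)
    w = upper + upper.T
    return ThresholdedGraph(w, density, connected=True) if as_graph else w


# Seizure diaries (baseline/follow-up counts per 4 weeks) and response
# labels of the 12 active-arm subjects of the clinical cohort the analysis
# was designed around; used as ground truth for the labeling rule.
CLINICAL_ACTIVE_DIARIES = [
    (80, 77, False),
    (1, 4, False),
    (1, 1, False),
    (1, 3, False),
    (3, 1, True),
    (10, 14, False),
    (9, 7, True),
    (7, 14, False),
    (12, 9, True),
    (5, 10, False),
    (28, 28, False),
    (1, 0, True),
]

# Sham-arm diaries of the same cohort (no response label applies).
CLINICAL_SHAM_DIARIES = [
    (56, 66), (2, 2), (3, 2), (6, 8), (2, 1), (14, 9), (6, 6), (6, 4),
]


@pytest.fixture(scope="session")
def clinical_subjects():
    subjects = []
    for i, (b, f, _) in enumerate(CLINICAL_ACTIVE_DIARIES):
        subjects.append(
            SubjectRecord(f"sub-{i + 1:02d}", "active", b, f, ("F7",))
        )
    for i, (b, f) in enumerate(CLINICAL_SHAM_DIARIES):
        subjects.append(
            SubjectRecord(f"sub-{i + 13:02d}", "sham", b, f, ("F8",))
        )
    return subjects


# Downscaled cohort shared by the heavier statistics/prediction tests:
# paper-sized arms (12 active / 4 true responders / 8 sham) on a 20-region
# parcellation so the density sweep stays connected and fast.
SMALL_COHORT_CONFIG = CohortConfig(
    n_regions=20,
    block_sizes=(5, 5, 5, 5),
    rho_between=0.2,
    n_active=12,
    n_sham=8,
    n_responders=4,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(SMALL_COHORT_CONFIG)
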