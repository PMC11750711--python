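import numpy as np
import pytest

from ovatriage import generate_cohort, score_cases
from ovatriage.config import CohortConfig


@pytest.fixture(scope="session")
def small_config():
    """A five-center cohort small enough for fast end-to-end checks but with
    enough examiners to satisfy the review-design minimums."""
    return CohortConfig(n_centers=5, cases_per_center=60)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=7)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    return score_cases(small_cohort["image_preds"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
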