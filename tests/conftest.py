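import numpy as np
import pytest

from addpheno import generate_cohort, make_scenario


@pytest.fixture(scope="session")
def well_separated():
    """A cohort with cleanly separated planted roles (no intermediates)."""
    cohort, truth = generate_cohort(make_scenario("well_separated", seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def paper_like_cocaine():
    cohort, truth = generate_cohort(make_scenario("paper_like_cocaine", seed=7))
    return cohort, truth


def binary_truth(truth: np.ndarray) -> np.ndarray:
    """Collapse planted roles to the two diagnostic roles (intermediates
    count as resilient for agreement checks on separable fixtures)."""
    return np.where(truth == "vulnerable", "vulnerable", "resilient").astype(object)
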