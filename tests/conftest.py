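import pytest

from triage_econ.cohort import CohortSpec, generate
from triage_econ.records import truth_map


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient synthetic cohort shared by read-only tests."""
    return generate(CohortSpec(n=60, seed=7))


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return truth_map(small_cohort.truth)


@pytest.fixture(scope="session")
def full_cohort():
    """A cohort at the reference size (465 patients)."""
    return generate(CohortSpec(n=465, seed=11))
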