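import pytest

from methmarker import SimulationConfig, simulate_cohort
from methmarker.core import CohortSet


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic cohort, shared read-only across the session."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def screening_ids(bundle):
    return [s.sample_id for s in bundle.samples if s.cohort_set is CohortSet.screening]


@pytest.fixture(scope="session")
def outcomes(bundle):
    return {s.sample_id: bool(s.pcr) for s in bundle.samples if s.pcr is not None}


@pytest.fixture(scope="session")
def ann_map(bundle):
    return {a.probe_id: a for a in bundle.annotation}
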