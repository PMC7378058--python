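import numpy as np
import pytest

from radsurv.cohort import CohortSpec, generate_cohort


def records_arrays(records):
    """Convenience: list of SurvivalRecord -> (time, event) arrays."""
    return (np.array([r.time for r in records]),
            np.array([r.event for r in records]))


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-case default-parameter cohort shared across tests."""
    spec = CohortSpec(n_cases=24, seed=5)
    cases, records = generate_cohort(spec)
    return spec, cases, records


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
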