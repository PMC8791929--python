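import numpy as np
import pytest

from tp53hit.cohort import (
    FIXTURE_RELAPSE_ACQUISITIONS,
    diagnosis_fixture_config,
    generate_cohort,
    generate_relapse_pairs,
)
from tp53hit.pipeline import analyze_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """Deterministic noise-free 143-patient cohort (reference composition)."""
    return generate_cohort(diagnosis_fixture_config(seed=1))


@pytest.fixture(scope="session")
def fixture_analysis(fixture_cohort):
    """(cn_calls, variants, statuses) of the deterministic cohort."""
    return analyze_cohort(fixture_cohort)


@pytest.fixture(scope="session")
def fixture_relapse(fixture_cohort):
    """53-pair relapse re-assessment with the exact 8/4/2 acquisition pattern."""
    return generate_relapse_pairs(
        fixture_cohort,
        deterministic_acquisitions=FIXTURE_RELAPSE_ACQUISITIONS,
        n_pairs=53,
        n_altered=9,
    )


@pytest.fixture(scope="session")
def fixture_relapse_analysis(fixture_relapse):
    return analyze_cohort(fixture_relapse)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
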