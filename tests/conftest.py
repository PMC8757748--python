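import numpy as np
import pytest

from cufflessbp.config import RunConfig
from cufflessbp.pipeline import prepare_sessions
from cufflessbp.protocol import screen_sessions
from cufflessbp.simulate import (CohortConfig, generate_cohort,
                                 generate_participant, synthesize_record)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def profile():
    return generate_participant(CohortConfig(), 42)


@pytest.fixture(scope="session")
def clean_record(profile):
    """60-s artifact-free record at 60 bpm with known truth."""
    return synthesize_record(profile, 120.0, 80.0, 60.0, 60.0, 7)


@pytest.fixture(scope="session")
def small_cohort():
    """20-participant cohort, 3 sessions each, exact 1:1:3:3:2 shares.

    Too small for the count quotas of the full protocol, so the audit is
    skipped at generation time.
    """
    cc = CohortConfig(n_participants=20, n_extra_sessions=0)
    return generate_cohort(cc, 11, check_quotas=False)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Prepared + screened session table of the small cohort."""
    prepared = prepare_sessions(small_cohort)
    retained, audit = screen_sessions(prepared)
    return retained, audit


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
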