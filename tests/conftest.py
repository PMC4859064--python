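import numpy as np
import pytest

from revmot import (CohortConfig, OraclePolicy, SubjectParameters, TaskConfig,
                    generate_cohort, simulate_session)


@pytest.fixture(scope="session")
def oracle_session():
    """One default 300-trial session under the oracle policy."""
    return simulate_session(TaskConfig(), OraclePolicy(), rng_seed=123)


@pytest.fixture(scope="session")
def default_params():
    return SubjectParameters(alpha=0.5, kappa=0.3, rho_rew=1.2, rho_pun=-1.1,
                             q_init=0.2)


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-subject synthetic cohort for structural tests."""
    from dataclasses import replace

    return generate_cohort(replace(CohortConfig(), n_subjects=20), seed=42)
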