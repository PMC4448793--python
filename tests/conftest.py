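import numpy as np
import pytest

from exitchoice import (
    CrowdParams,
    EnvironmentConfig,
    build_environment,
    run_evacuation,
)
from exitchoice.cohort import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def control_env():
    return build_environment(EnvironmentConfig())


@pytest.fixture(scope="session")
def wide_env():
    return build_environment(EnvironmentConfig(treatment_W=True))


@pytest.fixture(scope="session")
def control_history(control_env):
    return run_evacuation(control_env, CrowdParams(), seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """64-participant cohort (8 per condition) for fast integration tests."""
    design = CohortDesign(n_per_condition=8, seed=42)
    return generate_cohort(design, keep_histories=False)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort: 8 conditions x 58 participants = 464."""
    design = CohortDesign(seed=20240101)
    return generate_cohort(design, keep_histories=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
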