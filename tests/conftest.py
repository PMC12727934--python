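import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort (2 subjects/group, 24 s) for pipeline tests."""
    from strokeeg.simulate import SimConfig, generate_cohort

    return generate_cohort(
        SimConfig(n_subjects_per_group=2, duration_s=24.0, fs=250.0, master_seed=11)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (4 x 10 subjects, 60 s at 250 Hz)."""
    from strokeeg.simulate import SimConfig, generate_cohort

    return generate_cohort(SimConfig(master_seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
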