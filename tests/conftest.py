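import numpy as np
import pytest
from hypothesis import settings

from triscreen.synthetic import default_cohort_spec, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference_spec():
    return default_cohort_spec()


@pytest.fixture(scope="session")
def small_cohort(reference_spec):
    """One 40+40 cohort from the reference calibration."""
    return generate_cohort(reference_spec, seed=42)


@pytest.fixture(scope="session")
def labels(small_cohort):
    return small_cohort["group"].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
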