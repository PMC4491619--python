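import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from alphamark.preprocess import Recording, common_average_reference, segment_epochs
from alphamark.synth import SubjectSpec, generate_subject

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_subject() -> Recording:
    """A 60-s cohort-default synthetic subject (alpha peak at 10.9 Hz)."""
    return generate_subject(SubjectSpec(seed=1234, duration=60.0))


@pytest.fixture(scope="session")
def default_epochs(default_subject):
    return segment_epochs(common_average_reference(default_subject))


@pytest.fixture()
def tone_recording() -> Recording:
    """Two channels carrying a pure 10 Hz unit sinusoid."""
    t = np.arange(0, 20.0, 1.0 / 250.0)
    x = np.sin(2 * np.pi * 10.0 * t)
    return Recording(channel_labels=["A", "B"], sampling_rate=250.0,
                     samples=np.vstack([x, x]), reference="other")
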