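import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wheezefactor import AudioSegment, SyntheticSegmentSpec, generate_wheeze

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def mp1_segment():
    """Clean monophonic Type 1 tone at 300 Hz, 0.5 s, no drift."""
    return generate_wheeze(
        SyntheticSegmentSpec("MP1", f0=300.0, fm_depth=0.0, duration=0.5, seed=1)
    )


@pytest.fixture
def pp_segment():
    """Clean polyphonic tone pair at 250/430 Hz, 0.5 s, no drift."""
    return generate_wheeze(
        SyntheticSegmentSpec(
            "PP", f0=[250.0, 430.0], partial_amplitudes=[1.0, 1.0],
            fm_depth=0.0, duration=0.5, seed=2,
        )
    )


@pytest.fixture
def sine_segment():
    """Plain 250 Hz sinusoid, 1 s at 4096 Hz."""
    t = np.arange(4096) / 4096
    return AudioSegment(np.sin(2 * np.pi * 250.0 * t), 4096)
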