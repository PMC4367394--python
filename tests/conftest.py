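import numpy as np
import pytest

from ecgalarm import ScenarioSpec, generate_cohort, generate_recording
from ecgalarm.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_recording():
    """Default 120-s session, no PVCs, no noise bursts."""
    return generate_recording(ScenarioSpec(seed=7))


@pytest.fixture(scope="session")
def pvc_cohort():
    """Six subjects with PVC-bearing recordings (subject-varied noise)."""
    return generate_cohort(6, ScenarioSpec(pvc_rate=0.08), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
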