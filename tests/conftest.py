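import numpy as np
import pytest

from eegdtf.montage import default_montage
from eegdtf.recording import EEGRecording
from eegdtf.synthetic import CohortSpec, generate_cohorts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def montage():
    return default_montage()


@pytest.fixture
def small_recording(rng, montage):
    """A 20-s, 250 Hz, 32-channel noise recording."""
    data = rng.standard_normal((32, 5000))
    return EEGRecording(
        data=data, channel_labels=montage.channel_labels, sample_rate=250.0,
        subject_id="S001", group="NC", moca=27.0,
    )


@pytest.fixture(scope="session")
def tiny_cohorts():
    """3+3 subjects, 20 s at 125 Hz, no injected effects (shared across tests)."""
    spec = CohortSpec(n_subjects_per_group=3, duration_s=20.0,
                      sample_rate_hz=125.0, seed=42)
    return generate_cohorts(spec)
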