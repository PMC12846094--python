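import numpy as np
import pytest

from semgfatigue.preprocessing import preprocess_recording
from semgfatigue.segmentation import label_dataset, slide_windows
from semgfatigue.synth import SubjectProfile, simulate_subject


@pytest.fixture(scope="session")
def fatiguing_profile() -> SubjectProfile:
    """Short strong-effect session: cheap to simulate, clear drift."""
    return SubjectProfile(
        subject_id="S01",
        duration_s=30.0,
        rep_period_s=1.0,
        baseline_rms=0.15,
        rms_gain_end=2.0,
        mnf_start=120.0,
        mnf_end=70.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def recording(fatiguing_profile):
    return simulate_subject(fatiguing_profile)


@pytest.fixture(scope="session")
def processed(recording):
    return preprocess_recording(recording)


@pytest.fixture(scope="session")
def segments(processed):
    return slide_windows(processed)


@pytest.fixture(scope="session")
def labeled(segments):
    return label_dataset(segments)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
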