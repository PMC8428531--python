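import numpy as np
import pytest

from emoeeg.synthetic import SubjectProfile, synthesize_subject_recording
from emoeeg.preprocessing import segment_epochs

FS = 250.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_profile():
    return SubjectProfile(artifact_rate=0.0)


@pytest.fixture(scope="session")
def clean_recording(clean_profile):
    return synthesize_subject_recording(clean_profile, "negative", 8.0, FS, seed=7)


@pytest.fixture(scope="session")
def blink_recording():
    prof = SubjectProfile(artifact_rate=10.0)
    return synthesize_subject_recording(prof, "negative", 8.0, FS, seed=8)


@pytest.fixture(scope="session")
def clean_epochs(clean_recording):
    return segment_epochs(clean_recording, 1.0)
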