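import numpy as np
import pytest

from painq import synth


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 60-s record at 75 bpm with modest HRV."""
    profile = synth.SubjectProfile(
        "clean", base_heart_rate=75.0, hrv_sdnn=0.03,
        noise=synth.NoiseAmplitudes(0.0, 0.0, 0.0))
    return synth.generate_record(profile, 60.0, seed=11)


@pytest.fixture(scope="session")
def noisy_record():
    """60-s record with the default (moderate) noise mix."""
    profile = synth.SubjectProfile(
        "noisy", base_heart_rate=80.0, hrv_sdnn=0.04, pain_class="medium")
    return synth.generate_record(profile, 60.0, seed=12)


@pytest.fixture(scope="session")
def ten_second_segment(noisy_record):
    from painq import preprocess

    filtered = preprocess.bandpass_filter(noisy_record)
    return preprocess.normalize(preprocess.segment_record(filtered)[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
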