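import numpy as np
import pytest

from wheelbeat.synthetic import (
    NoiseProfile,
    SubjectMorphology,
    simulate_clean_ecg,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def morphology():
    return SubjectMorphology(mean_hr_bpm=60.0)


@pytest.fixture(scope="session")
def clean_stream(morphology):
    """30 s of clean synthetic ECG at 1 kHz, 60 bpm."""
    return simulate_clean_ecg(morphology, duration=30.0, fs=1000.0, seed=42)


@pytest.fixture(scope="session")
def cohort_streams():
    """Six noisy subjects, two trips each — the end-to-end working set."""
    return simulate_cohort(6, 2, trip_duration=120.0, fs=1000.0, seed=7,
                           noise=NoiseProfile())


@pytest.fixture(scope="session")
def cohort_dct(cohort_streams):
    from wheelbeat.pipeline import cohort_dataset

    return cohort_dataset(cohort_streams, scheme="DCT")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
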