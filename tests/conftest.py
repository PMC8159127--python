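import numpy as np
import pytest

from biodimred import (
    P300Config,
    SegmentationSpec,
    detect_r_peaks,
    generate_ecg_record,
    generate_p300_record,
    make_ecg_pattern_set,
    segment_r_centered,
)


@pytest.fixture(scope="session")
def clean_n_record():
    """Noiseless 30-beat normal-sinus record at 360 Hz."""
    return generate_ecg_record(["N"] * 30, fs=360, rr_mean=0.8, seed=11)


@pytest.fixture(scope="session")
def clean_patterns(clean_n_record):
    peaks = detect_r_peaks(clean_n_record)
    return segment_r_centered(clean_n_record, peaks, SegmentationSpec())


@pytest.fixture(scope="session")
def small_pattern_set():
    """Balanced 8-class set, 12 beats per class, default study conditions."""
    return make_ecg_pattern_set(12, seed=7)


@pytest.fixture(scope="session")
def p300_record():
    """Moderate-size synthetic oddball record (60 trials)."""
    return generate_p300_record(P300Config(n_trials=60, seed=21))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
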