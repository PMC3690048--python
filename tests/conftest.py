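import numpy as np
import pytest

from cwtcardio import ECGSimSpec, gen_ecg


@pytest.fixture(scope="session")
def clean_ecg_75bpm():
    """60 s clean synthetic ECG at 75 bpm with ground truth."""
    record, truth_t, truth_cls = gen_ecg(
        ECGSimSpec(duration_s=60.0, hr_bpm=75.0, seed=1)
    )
    return record, truth_t, truth_cls


@pytest.fixture(scope="session")
def ecg_with_extrasystoles():
    """120 s, 80 bpm record with six inserted premature beats."""
    extrasystoles = [(idx, 0.45, 0.4) for idx in (20, 45, 70, 95, 120, 145)]
    record, truth_t, truth_cls = gen_ecg(
        ECGSimSpec(duration_s=120.0, hr_bpm=80.0, seed=3,
                   extrasystoles=extrasystoles)
    )
    return record, truth_t, truth_cls


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
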