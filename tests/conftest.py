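import numpy as np
import pytest

from f0track.preprocess import average_reference, bandpass_array
from f0track.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated experiment, shared across tests."""
    spec = SyntheticSpec(
        n_words=150, n_parts=3, n_subjects=2, n_channels=4, snr_db=0.0, seed=7
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_dataset_eeg(small_dataset):
    """Preprocessed (band-passed, average-referenced) EEG parts per subject."""
    return [
        [average_reference(bandpass_array(e, 1000.0)) for e in subject_parts]
        for subject_parts in small_dataset.eeg_parts_per_subject
    ]
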