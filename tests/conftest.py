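import numpy as np
import pytest

from fretfold import (
    AcquisitionModel,
    Condition,
    compute_fret,
    simulate_dataset,
    two_state_scheme,
)


@pytest.fixture(scope="session")
def small_two_state_dataset():
    """60 noiseless-channel traces from a moderately fast two-state scheme.

    Emission jitter (sd 0.05) is the only noise source, as in a
    shot-noise-limited proximity-ratio measurement.
    """
    scheme = two_state_scheme(k_fold=0.84, k_unfold=0.84)
    acq = AcquisitionModel(frame_interval=0.050, n_frames=600)
    return simulate_dataset(scheme, acq, Condition(), n_traces=60, seed=7)


@pytest.fixture(scope="session")
def small_fret_traces(small_two_state_dataset):
    return [compute_fret(t) for t in small_two_state_dataset.traces]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
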