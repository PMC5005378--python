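import numpy as np
import pytest

from circasleep import Hypnogram, make_schedule, preprocess, simulate_eeg_emg
from circasleep.synthetic import SimParams


@pytest.fixture(scope="session")
def ld12():
    return make_schedule(24.0, 0.5, n_days=1)


@pytest.fixture(scope="session")
def default_params():
    return SimParams()


@pytest.fixture(scope="session")
def wake_recording_pair(ld12):
    """Preprocessed 10-min wake recordings at kappa=0 and kappa=0.8, with the
    shared hypnogram (used by the coupling tests)."""
    hyp = Hypnogram(states=np.full(150, "W"), provenance="simulated")
    recs = {}
    for kappa in (0.0, 0.8):
        params = SimParams(coupling_kappa=kappa)
        recs[kappa] = preprocess(simulate_eeg_emg(hyp, ld12, params, seed=5))
    return hyp, recs
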