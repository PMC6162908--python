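import numpy as np
import pytest

from mibci.data import epoch_trialset
from mibci.synth import SyntheticConfig, simulate_trialset


@pytest.fixture(scope="session")
def small_epoched_trialset():
    """30 trials/class of strong-ERD synthetic EEG, epoched over [4, 6] s."""
    cfg = SyntheticConfig(n_trials_per_class=30, seed=7)
    return epoch_trialset(simulate_trialset(cfg), (4.0, 6.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
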