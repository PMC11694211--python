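import numpy as np
import pytest

from snatchlab import SubjectInfo, process_trial
from snatchlab.simulate import TrialParams, generate_trial


@pytest.fixture(scope="session")
def noiseless_trial():
    """Default-parameter trial with sensor noise off, processed end to end."""
    p = TrialParams(noise_sd_pos=0.0, noise_sd_force=0.0, seed=11)
    raw, truth = generate_trial(p)
    subject = SubjectInfo("S01", p.body_height, p.body_mass)
    signals, events, feats = process_trial(raw, subject)
    return p, raw, truth, signals, events, feats


@pytest.fixture(scope="session")
def noisy_trial():
    """Default trial at the generator's default sensor-noise levels."""
    p = TrialParams(seed=23)
    raw, truth = generate_trial(p)
    subject = SubjectInfo("S01", p.body_height, p.body_mass)
    signals, events, feats = process_trial(raw, subject)
    return p, raw, truth, signals, events, feats


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
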