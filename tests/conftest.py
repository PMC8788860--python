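import numpy as np
import pytest

from wdi.behavior import Stimulus, TrialRecord
from wdi.synthetic import SimParams, generate_session, simulate_dff


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trial(stimulus="whisker", stim_time=5.0, licks=(), **kw):
    return TrialRecord(
        trial_id=kw.pop("trial_id", 0),
        stimulus=Stimulus(stimulus),
        stim_time=stim_time,
        lick_times=tuple(sorted(licks)),
        **kw,
    )


@pytest.fixture(scope="session")
def small_session():
    """One simulated session shared across read-only tests."""
    params = SimParams(n_s2p=10, n_m1p=10, session_length=300.0, seed=42)
    behavior, gt = generate_session(params)
    dff = simulate_dff(behavior, gt, params)
    return params, behavior, gt, dff
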