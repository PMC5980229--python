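import numpy as np
import pytest

from avoidance_ephys.data_model import ClassifierConfig, SessionEvents, TrialEvents
from avoidance_ephys.synthetic import SimConfig, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def ccfg():
    return ClassifierConfig()


@pytest.fixture
def small_sim_config():
    """Reduced cohort for pipeline-level tests (same structure, fewer units)."""
    return SimConfig(composition={
        "avoidance": {"excited": 6, "inhibited_brief": 4,
                      "inhibited_sustained": 1, "none": 30},
        "naive": {"excited": 4, "inhibited_brief": 1,
                  "inhibited_sustained": 0, "none": 28},
        "fear": {"excited": 5, "inhibited_brief": 1,
                 "inhibited_sustained": 0, "none": 32},
    })


@pytest.fixture
def session(rng):
    """One avoidance session (9 trials, tones + shocks + platform events)."""
    return simulate_session(SimConfig(), "avoidance", rng)


def make_trial(trial_id=1, onset=100.0, tone_s=30.0, shock=True, **kwargs):
    shock_iv = (onset + tone_s - 2.0, onset + tone_s) if shock else None
    return TrialEvents(trial_id=trial_id, tone_onset_s=onset,
                       tone_duration_s=tone_s, shock_interval_s=shock_iv,
                       **kwargs)


def make_session(trials, session_id="s1"):
    return SessionEvents(session_id=session_id, trials=trials)
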