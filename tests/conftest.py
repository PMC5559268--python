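import numpy as np
import pytest

from gonogo import (
    GO_ENVELOPE,
    FULL_NOGO_ENVELOPE,
    ParametricAgent,
    RandomLicker,
    StimulusConfig,
    TaskConfig,
    TransitionDetector,
    TrialRecord,
    run_session,
)


@pytest.fixture
def stim_config():
    return StimulusConfig(seed=7)


@pytest.fixture
def fast_stim_config():
    """Low sample rate to keep waveform tests cheap."""
    return StimulusConfig(sample_rate_hz=1000.0, seed=7)


@pytest.fixture
def task_config():
    return TaskConfig(n_trials=250, seed=11)


def make_window(n_go, n_nogo, n_hits, n_crs):
    """Build a trial list with exact hit / correct-rejection counts."""
    trials = []
    i = 1
    for k in range(n_go):
        hit = k < n_hits
        trials.append(
            TrialRecord(
                index=i,
                stimulus_class="GO",
                stimulus_id="GO",
                lick_times_ms=(900.0,) if hit else (),
                outcome="hit" if hit else "miss",
                rewarded=hit,
            )
        )
        i += 1
    for k in range(n_nogo):
        cr = k < n_crs
        trials.append(
            TrialRecord(
                index=i,
                stimulus_class="NOGO",
                stimulus_id="NOGO",
                lick_times_ms=() if cr else (900.0,),
                outcome="correct_rejection" if cr else "false_alarm",
                rewarded=False,
            )
        )
        i += 1
    return trials


@pytest.fixture
def transition_session():
    agent = TransitionDetector(
        GO_ENVELOPE, FULL_NOGO_ENVELOPE, decision_latency_ms=100.0, fa_rate=0.1
    )
    return run_session(agent, TaskConfig(n_trials=250, seed=3))


@pytest.fixture
def random_session():
    return run_session(RandomLicker(0.5), TaskConfig(n_trials=250, seed=5))
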