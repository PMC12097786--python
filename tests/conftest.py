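import numpy as np
import pandas as pd
import pytest

from subneuro.behavior import apply_qc, label_outcomes
from subneuro.config import NeuronProfile, ObserverModel, TaskConfig
from subneuro.synth import simulate_behavior


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def task():
    return TaskConfig()


@pytest.fixture
def observer():
    return ObserverModel()


@pytest.fixture
def labeled_session(task, observer):
    """One labeled + QC'd behavioral session (71 trials, default observer)."""
    trials = simulate_behavior(task, observer, np.random.default_rng(7))
    return apply_qc(label_outcomes(trials))


def make_trials(n_stim=40, n_catch=10, outcomes=None, seed=0, task=None):
    """Deterministic hand-built trial table with assigned outcomes.

    ``outcomes`` (over stimulus trials) defaults to alternating hit/miss.
    Stimulus onsets are spread evenly over the stimulation window.
    """
    task = task or TaskConfig()
    rng = np.random.default_rng(seed)
    n = n_stim + n_catch
    is_catch = np.zeros(n, dtype=bool)
    catch_pos = rng.choice(n, size=n_catch, replace=False)
    is_catch[catch_pos] = True
    if outcomes is None:
        outcomes = ["hit" if i % 2 == 0 else "miss" for i in range(n_stim)]
    rows, t, k = [], 1.0, 0
    frac = np.linspace(0.05, 0.95, n_stim)
    for i in range(n):
        cue_onset = t
        cue_offset = cue_onset + task.cue_duration
        win_start = cue_offset + task.post_cue_delay
        if is_catch[i]:
            stim, amp, report = np.nan, np.nan, "no"
        else:
            stim = win_start + frac[k] * task.stim_window
            amp = 1.0
            report = "yes" if outcomes[k] == "hit" else "no"
            k += 1
        respond = win_start + task.stim_window + 0.75
        rows.append(
            dict(
                index=i,
                cue_onset=cue_onset,
                cue_offset=cue_offset,
                stim_onset=stim,
                amplitude=amp,
                respond_cue=respond,
                report=report,
            )
        )
        t = respond + task.iti
    return label_outcomes(pd.DataFrame(rows))
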