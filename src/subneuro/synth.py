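"""Synthetic session generator: behavior and spike trains with known truth.

A session is a sequence of trials (go cue, delayed stimulus or catch,
respond cue), a staircase-driven amplitude trace with observer reports, and
inhomogeneous-Poisson spike trains whose rate functions carry the configured
cue/task/sensory/perception modulations. Every downstream stage of the
analysis can therefore be tested against ground truth without clinical data.

Randomness is organized as named substreams of one master seed: behavior,
artifacts, and each neuron draw from independent children of
``numpy.random.SeedSequence(seed)``, so each component is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import ArtifactConfig, NeuronProfile, ObserverModel, TaskConfig
from .errors import ConfigurationError, DomainError

__all__ = [
    "SpikeTrain",
    "SyntheticSession",
    "simulate_trial_sequence",
    "staircase_update",
    "psychometric_p_yes",
    "simulate_report",
    "simulate_behavior",
    "simulate_spike_train",
    "simulate_artifacts",
    "simulate_session",
]

_ENVELOPE_DT = 0.001  # rate envelope resolution, seconds


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (seconds) for one putative neuron."""

    neuron_id: str
    timestamps: np.ndarray
    region: str = "STN"  # STN | thalamus
    unit_grade: str = "single"  # single | multi

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.timestamps) < 0):
            from .errors import ValidationError

            raise ValidationError(f"{self.neuron_id}: timestamps not sorted")


@dataclass
class SyntheticSession:
    """One simulated session: behavior, spikes, artifacts, and ground truth."""

    trials: pd.DataFrame
    spike_trains: list[SpikeTrain]
    truth: dict[str, NeuronProfile]
    artifact_epochs: np.ndarray  # (n, 2) start/end seconds
    seed: int
    session_length: float
    task: TaskConfig = field(default_factory=TaskConfig)


def simulate_trial_sequence(
    config: TaskConfig,
    rng: np.random.Generator | int,
    start_time: float = 1.0,
) -> pd.DataFrame:
    """Draw the event times for one session.

    Stimulus onsets are uniform over the stimulation window (i.e. between
    ``post_cue_delay`` and ``post_cue_delay + stim_window`` after cue
    offset); exactly ``round(catch_fraction * n_trials)`` trials are catch
    trials, in randomized positions. The respond cue follows the window end
    by a uniform 0.5-1 s delay.
    """
    config.validate()
    rng = np.random.default_rng(rng)
    n = config.n_trials
    is_catch = np.zeros(n, dtype=bool)
    is_catch[: config.n_catch] = True
    rng.shuffle(is_catch)

    rows = []
    t = float(start_time)
    for i in range(n):
        cue_onset = t
        cue_offset = cue_onset + config.cue_duration
        win_start = cue_offset + config.post_cue_delay
        win_end = win_start + config.stim_window
        stim_onset = np.nan if is_catch[i] else rng.uniform(win_start, win_end)
        respond_cue = win_end + rng.uniform(
            config.respond_delay_min, config.respond_delay_max
        )
        rows.append(
            dict(
                index=i,
                cue_onset=cue_onset,
                cue_offset=cue_offset,
                stim_onset=stim_onset,
                respond_cue=respond_cue,
            )
        )
        t = respond_cue + config.iti
    return pd.DataFrame(rows)


def staircase_update(amplitude: float, outcome: str, step: float = 0.05) -> float:
    """1-up/1-down multiplicative staircase: up 5% after a miss, down 5%
    after a hit, unchanged on catch trials (no stimulus, no update)."""
    if not amplitude > 0:
        raise DomainError(f"amplitude must be > 0, got {amplitude!r}")
    if outcome == "miss":
        return amplitude * (1.0 + step)
    if outcome == "hit":
        return amplitude * (1.0 - step)
    if outcome == "catch":
        return amplitude
    raise DomainError(f"unknown staircase outcome {outcome!r}")


def psychometric_p_yes(amplitude: float, observer: ObserverModel) -> float:
    """Detection probability for a stimulus of the given amplitude."""
    lo = observer.false_alarm_rate
    hi = 1.0 - observer.lapse_rate
    core = expit(observer.slope * np.log(amplitude / observer.threshold))
    return float(lo + (hi - lo) * core)


def simulate_report(
    amplitude: float,
    observer: ObserverModel,
    is_catch: bool,
    rng: np.random.Generator,
) -> bool:
    """One yes/no report: false-alarm rate on catch, psychometric otherwise."""
    observer.validate()
    p = observer.false_alarm_rate if is_catch else psychometric_p_yes(amplitude, observer)
    return bool(rng.random() < p)


def simulate_behavior(
    config: TaskConfig,
    observer: ObserverModel,
    rng: np.random.Generator | int,
    initial_amplitude: float = 1.0,
) -> pd.DataFrame:
    """Full behavioral session: trial sequence + staircase + reports.

    Returns a trial table with ``amplitude`` (NaN on catch trials) and
    ``report`` ("yes"/"no") columns added. Observer dropout blocks (if
    configured) force "no" reports on stimulus trials, producing the long
    miss runs the quality filter is designed to remove.
    """
    rng = np.random.default_rng(rng)
    observer.validate()
    trials = simulate_trial_sequence(config, rng)
    amplitude = float(initial_amplitude)
    if not amplitude > 0:
        raise DomainError("initial_amplitude must be > 0")

    amplitudes: list[float] = []
    reports: list[str] = []
    dropout_left = 0
    for _, tr in trials.iterrows():
        is_catch = not np.isfinite(tr.stim_onset)
        if observer.dropout_prob and dropout_left == 0:
            if rng.random() < observer.dropout_prob:
                dropout_left = observer.dropout_len
        if dropout_left > 0:
            dropout_left -= 1
            report = simulate_report(amplitude, observer, is_catch, rng) if is_catch else False
        else:
            report = simulate_report(amplitude, observer, is_catch, rng)
        if is_catch:
            amplitudes.append(np.nan)
        else:
            amplitudes.append(amplitude)
            amplitude = staircase_update(
                amplitude, "hit" if report else "miss", config.staircase_step
            )
        reports.append("yes" if report else "no")
    out = trials.copy()
    out["amplitude"] = amplitudes
    out["report"] = reports
    return out


def _rate_envelope(
    profile: NeuronProfile,
    trials: pd.DataFrame,
    session_length: float,
    task: TaskConfig,
) -> np.ndarray:
    """Piecewise rate function on a 1-ms grid (Hz)."""
    n = int(np.ceil(session_length / _ENVELOPE_DT))
    rate = np.full(n, profile.baseline_rate, dtype=float)

    def window(start: float, end: float) -> slice:
        i0 = max(0, int(round(start / _ENVELOPE_DT)))
        i1 = min(n, int(round(end / _ENVELOPE_DT)))
        return slice(i0, max(i0, i1))

    has_outcome = "outcome" in trials.columns
    for _, tr in trials.iterrows():
        if profile.cue_gain != 1.0:
            s = tr.cue_offset + profile.cue_latency
            rate[window(s, s + profile.cue_duration)] *= profile.cue_gain
        if profile.task_gain != 1.0:
            s = tr.cue_offset + task.post_cue_delay
            rate[window(s, s + task.stim_window)] *= profile.task_gain
        if np.isfinite(tr.stim_onset):
            if profile.sensory_gain != 1.0:
                s = tr.stim_onset + profile.sensory_latency
                rate[window(s, s + profile.sensory_duration)] *= profile.sensory_gain
            if profile.perception_gain != 1.0:
                if not has_outcome:
                    raise ConfigurationError(
                        "perception_gain requires trials with an 'outcome' column"
                    )
                if tr.outcome == "hit":
                    s = tr.stim_onset + profile.perception_latency
                    rate[window(s, s + profile.perception_duration)] *= (
                        profile.perception_gain
                    )
        if profile.drift_slope != 0.0:
            sl = window(tr.cue_onset, tr.respond_cue)
            t_rel = (np.arange(sl.start, sl.stop) * _ENVELOPE_DT) - tr.cue_onset
            rate[sl] += profile.drift_slope * t_rel

    if np.any(rate < 0):
        raise DomainError("rate envelope is negative; reduce drift or gains")
    return rate


def simulate_spike_train(
    profile: NeuronProfile,
    trials: pd.DataFrame,
    session_length: float,
    rng: np.random.Generator | int,
    task: TaskConfig | None = None,
    neuron_id: str = "n0",
    region: str = "STN",
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes by thinning, with a hard refractory floor.

    A homogeneous Poisson stream at the envelope maximum is thinned by the
    ratio ``rate(t) / rate_max``; accepted spikes closer than
    ``refractory_floor`` to the previous accepted spike are discarded.
    """
    profile.validate()
    rng = np.random.default_rng(rng)
    task = task or TaskConfig()
    rate = _rate_envelope(profile, trials, session_length, task)
    rmax = float(rate.max())
    n_cand = rng.poisson(rmax * session_length)
    times = np.sort(rng.uniform(0.0, session_length, n_cand))
    idx = np.minimum((times / _ENVELOPE_DT).astype(int), len(rate) - 1)
    keep = rng.random(n_cand) < rate[idx] / rmax
    times = times[keep]

    if profile.refractory_floor > 0 and len(times) > 1:
        accepted = [times[0]]
        for t in times[1:]:
            if t - accepted[-1] >= profile.refractory_floor:
                accepted.append(t)
        times = np.asarray(accepted)
    return SpikeTrain(neuron_id=neuron_id, timestamps=times, region=region)


def simulate_artifacts(
    config: ArtifactConfig,
    session_length: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Poisson process of blanking epochs; returns an (n, 2) start/end array."""
    config.validate()
    rng = np.random.default_rng(rng)
    n = rng.poisson(config.rate * session_length)
    starts = np.sort(rng.uniform(0.0, session_length, n))
    durations = rng.uniform(config.min_duration, config.max_duration, n)
    ends = np.minimum(starts + durations, session_length)
    return np.column_stack([starts, ends]) if n else np.empty((0, 2))


def simulate_session(
    profiles: list[NeuronProfile] | dict[str, NeuronProfile],
    seed: int,
    task: TaskConfig | None = None,
    observer: ObserverModel | None = None,
    artifacts: ArtifactConfig | None = None,
    initial_amplitude: float = 1.0,
    region: str = "STN",
) -> SyntheticSession:
    """Generate a complete session from one master seed.

    The seed is split into independent substreams (behavior, artifacts, one
    per neuron), so e.g. regenerating behavior alone reproduces the same
    trial table regardless of how many neurons are simulated.
    """
    task = task or TaskConfig()
    observer = observer or ObserverModel()
    artifacts = artifacts or ArtifactConfig()
    if isinstance(profiles, dict):
        named = dict(profiles)
    else:
        named = {f"n{i}": p for i, p in enumerate(profiles)}

    ss = np.random.SeedSequence(seed)
    beh_ss, art_ss, spikes_ss = ss.spawn(3)
    trials = simulate_behavior(
        task, observer, np.random.default_rng(beh_ss), initial_amplitude
    )
    # derived outcome needed before spikes: perception gains act on hits
    from .behavior import label_outcomes

    trials = label_outcomes(trials)
    session_length = float(trials.respond_cue.iloc[-1] + task.iti)
    artifact_epochs = simulate_artifacts(
        artifacts, session_length, np.random.default_rng(art_ss)
    )
    trains = []
    for child, (nid, profile) in zip(spikes_ss.spawn(len(named)), named.items()):
        trains.append(
            simulate_spike_train(
                profile,
                trials,
                session_length,
                np.random.default_rng(child),
                task=task,
                neuron_id=nid,
                region=region,
            )
        )
    return SyntheticSession(
        trials=trials,
        spike_trains=trains,
        truth=named,
        artifact_epochs=artifact_epochs,
        seed=int(seed),
        session_length=session_length,
        task=task,
    )
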