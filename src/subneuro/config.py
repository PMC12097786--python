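"""Configuration objects for task, observer, and neuron ground truth.

The task geometry follows an intraoperative vibrotactile detection protocol:
a 300-ms auditory go cue, a 500-ms delay, a 2-s window inside which a 100-ms
stimulus may occur (uniformly), 20% catch trials without a stimulus, and a
respond cue 0.5-1 s after the window closes prompting a verbal yes/no report.
Stimulus amplitude is driven by a 1-up/1-down staircase with 5% steps, which
converges onto the 50% detection point.

``NeuronProfile`` encodes the ground-truth rate modulations of a simulated
neuron as multiplicative gains with onset latency and duration, so that
parameter-recovery tests can compare analysis output against known truth.
Gains below 1 encode suppression, the predominant direction in subcortical
recordings of this kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

__all__ = [
    "TaskConfig",
    "ObserverModel",
    "NeuronProfile",
    "ArtifactConfig",
    "load_config",
]


@dataclass(frozen=True)
class TaskConfig:
    """Trial timing and staircase parameters (all durations in seconds)."""

    cue_duration: float = 0.3
    post_cue_delay: float = 0.5
    stim_window: float = 2.0
    stim_duration: float = 0.1
    catch_fraction: float = 0.2
    respond_delay_min: float = 0.5
    respond_delay_max: float = 1.0
    n_trials: int = 71
    staircase_step: float = 0.05
    # quiet inter-trial interval after the respond cue; long enough to hold
    # the verbal response and the 500-ms pre-cue baseline of the next trial
    iti: float = 2.0

    def validate(self) -> None:
        durations = {
            "cue_duration": self.cue_duration,
            "post_cue_delay": self.post_cue_delay,
            "stim_window": self.stim_window,
            "stim_duration": self.stim_duration,
            "iti": self.iti,
        }
        for name, value in durations.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be > 0, got {value!r}")
        if not (0 <= self.catch_fraction < 1):
            raise ConfigurationError(
                f"catch_fraction must be in [0, 1), got {self.catch_fraction!r}"
            )
        if self.respond_delay_min > self.respond_delay_max:
            raise ConfigurationError("respond_delay_min must be <= respond_delay_max")
        if self.respond_delay_min < 0:
            raise ConfigurationError("respond delays must be nonnegative")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if not (0 < self.staircase_step < 1):
            raise ConfigurationError("staircase_step must be in (0, 1)")

    @property
    def n_catch(self) -> int:
        return round(self.catch_fraction * self.n_trials)


@dataclass(frozen=True)
class ObserverModel:
    """Stationary psychometric observer.

    Detection probability on stimulus trials is a logistic function of
    log-amplitude with a false-alarm floor and a lapse ceiling::

        p(yes | a) = fa + (1 - fa - lapse) * expit(slope * log(a / threshold))

    so at ``a == threshold`` with ``fa == lapse == 0`` the observer detects
    with probability exactly 0.5. Catch trials are reported "yes" with
    probability ``false_alarm_rate``. ``dropout_prob``/``dropout_len`` add a
    nonstationary failure mode — per trial, a block of forced misses may
    start — emulating attention lapses after anesthesia; sessions generated
    with it exercise the behavioral quality filter.
    """

    threshold: float = 1.0
    slope: float = 8.0
    lapse_rate: float = 0.02
    false_alarm_rate: float = 0.24
    dropout_prob: float = 0.0
    dropout_len: int = 10

    def validate(self) -> None:
        if not self.threshold > 0:
            raise ConfigurationError("threshold must be > 0")
        if not self.slope > 0:
            raise ConfigurationError("slope must be > 0")
        for name in ("lapse_rate", "false_alarm_rate", "dropout_prob"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")
        if self.dropout_len < 1:
            raise ConfigurationError("dropout_len must be >= 1")


@dataclass(frozen=True)
class NeuronProfile:
    """Ground-truth rate modulation of one simulated neuron.

    The instantaneous rate is ``baseline_rate`` multiplied by every gain
    whose window is active, plus a linear within-trial drift anchored at cue
    onset. Latencies are relative to cue offset (cue effect) or stimulus
    onset (sensory/perception effects); the task gain spans the whole
    stimulation window. The perception gain applies on hit trials only.
    """

    baseline_rate: float = 20.0
    cue_gain: float = 1.0
    cue_latency: float = 0.0
    cue_duration: float = 0.5
    task_gain: float = 1.0
    sensory_gain: float = 1.0
    sensory_latency: float = 0.211
    sensory_duration: float = 0.126
    perception_gain: float = 1.0
    perception_latency: float = 0.160
    perception_duration: float = 0.100
    drift_slope: float = 0.0  # Hz per second, within-trial, cue-anchored
    refractory_floor: float = 0.002

    def validate(self) -> None:
        if not self.baseline_rate > 0:
            raise ConfigurationError("baseline_rate must be > 0")
        for name in ("cue_gain", "task_gain", "sensory_gain", "perception_gain"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0 (values < 1 suppress)")
        for name in (
            "cue_latency",
            "sensory_latency",
            "perception_latency",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("cue_duration", "sensory_duration", "perception_duration"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.refractory_floor < 0:
            raise ConfigurationError("refractory_floor must be >= 0")


@dataclass(frozen=True)
class ArtifactConfig:
    """Poisson process of blanking epochs (vocal-response cross-talk)."""

    rate: float = 0.02  # epochs per second
    min_duration: float = 0.2
    max_duration: float = 1.0

    def validate(self) -> None:
        if self.rate < 0:
            raise ConfigurationError("artifact rate must be >= 0")
        if not (0 < self.min_duration <= self.max_duration):
            raise ConfigurationError("artifact durations must satisfy 0 < min <= max")


_SECTIONS: dict[str, type] = {
    "task": TaskConfig,
    "observer": ObserverModel,
    "artifacts": ArtifactConfig,
}


def _build(cls: type, payload: dict[str, Any], context: str):
    try:
        obj = cls(**payload)
    except TypeError as exc:
        raise ConfigurationError(f"{context}: {exc}") from None
    obj.validate()
    return obj


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON config file into validated dataclasses.

    Recognized sections: ``task``, ``observer``, ``artifacts`` (mappings),
    ``neurons`` (list of NeuronProfile mappings), plus free-form scalar
    entries (e.g. ``n_sessions``, ``region``) passed through untouched.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw)}")
    out: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            out[key] = _build(_SECTIONS[key], dict(value or {}), key)
        elif key == "neurons":
            out[key] = [
                _build(NeuronProfile, dict(entry or {}), f"neurons[{i}]")
                for i, entry in enumerate(value or [])
            ]
        else:
            out[key] = value
    return out


def config_to_dict(config: dict[str, Any]) -> dict[str, Any]:
    """Inverse of :func:`load_config` for provenance hashing / round-trips."""
    out: dict[str, Any] = {}
    for key, value in config.items():
        if key == "neurons":
            out[key] = [asdict(p) for p in value]
        elif hasattr(value, "__dataclass_fields__"):
            out[key] = asdict(value)
        else:
            out[key] = value
    return out
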