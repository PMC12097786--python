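"""Session interchange format: plain-CSV bundle per session.

A session directory holds::

    session.json    metadata: participant, region, diagnosis, seed, task
                    config, declared neurons, provenance (version + config hash)
    trials.csv      index, cue_onset, cue_offset, stim_onset (empty on catch),
                    amplitude, respond_cue, report
    spikes.csv      neuron_id, timestamp
    artifacts.csv   start, end

All times are seconds from session start, double precision; CSV headers are
mandatory and files are UTF-8. ``read_session`` validates ordering,
referential integrity, and trial-time monotonicity, naming the offending
file and row in every error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import TaskConfig, config_to_dict
from .errors import ValidationError
from .synth import SpikeTrain, SyntheticSession

__all__ = ["SessionData", "write_session", "read_session", "find_sessions"]

TRIAL_COLUMNS = [
    "index",
    "cue_onset",
    "cue_offset",
    "stim_onset",
    "amplitude",
    "respond_cue",
    "report",
]


@dataclass
class SessionData:
    """In-memory session as read back from a bundle."""

    trials: pd.DataFrame
    spike_trains: list[SpikeTrain]
    artifact_epochs: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def task(self) -> TaskConfig:
        return TaskConfig(**self.meta.get("task", {}))


def _config_hash(payload: dict[str, Any]) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_session(
    session: SyntheticSession | SessionData,
    path: str | Path,
    participant: str = "synthetic",
    region: str | None = None,
    diagnosis: str = "synthetic",
) -> Path:
    """Write a session bundle; returns the session directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    if isinstance(session, SyntheticSession):
        trials = session.trials
        trains = session.spike_trains
        artifacts = session.artifact_epochs
        task_dict = config_to_dict({"task": session.task})["task"]
        seed = session.seed
    else:
        trials = session.trials
        trains = session.spike_trains
        artifacts = session.artifact_epochs
        task_dict = session.meta.get("task", {})
        seed = session.meta.get("seed")

    trials[TRIAL_COLUMNS].to_csv(path / "trials.csv", index=False)
    spikes = pd.DataFrame(
        [
            {"neuron_id": tr.neuron_id, "timestamp": t}
            for tr in trains
            for t in tr.timestamps
        ],
        columns=["neuron_id", "timestamp"],
    )
    spikes.to_csv(path / "spikes.csv", index=False)
    pd.DataFrame(artifacts, columns=["start", "end"]).to_csv(
        path / "artifacts.csv", index=False
    )
    meta = {
        "participant": participant,
        "region": region or (trains[0].region if trains else "STN"),
        "diagnosis": diagnosis,
        "seed": seed,
        "task": task_dict,
        "neurons": [
            {"neuron_id": tr.neuron_id, "region": tr.region, "unit_grade": tr.unit_grade}
            for tr in trains
        ],
        "provenance": {
            "tool": f"subneuro {__version__}",
            "config_hash": _config_hash(task_dict),
        },
    }
    (path / "session.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return path


def _require(path: Path) -> Path:
    if not path.exists():
        raise ValidationError(f"missing bundle file: {path}")
    return path


def read_session(path: str | Path) -> SessionData:
    """Read and validate a session bundle."""
    path = Path(path)
    meta = json.loads(_require(path / "session.json").read_text(encoding="utf-8"))
    trials = pd.read_csv(_require(path / "trials.csv"))
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trials.csv: missing columns {missing}")

    for i, row in trials.iterrows():
        if not row.cue_onset < row.cue_offset:
            raise ValidationError(
                f"trials.csv row {i}: cue_offset must follow cue_onset"
            )
        if not row.cue_offset < row.respond_cue:
            raise ValidationError(
                f"trials.csv row {i}: respond_cue must follow cue_offset"
            )
        if np.isfinite(row.stim_onset) and not (
            row.cue_offset < row.stim_onset < row.respond_cue
        ):
            raise ValidationError(
                f"trials.csv row {i}: stim_onset outside the trial"
            )
    onsets = trials["cue_onset"].to_numpy()
    if np.any(np.diff(onsets) <= 0):
        bad = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
        raise ValidationError(f"trials.csv row {bad}: trial times not increasing")

    spikes = pd.read_csv(_require(path / "spikes.csv"))
    declared = {n["neuron_id"]: n for n in meta.get("neurons", [])}
    trains: list[SpikeTrain] = []
    for nid, group in spikes.groupby("neuron_id", sort=True):
        if str(nid) not in declared:
            raise ValidationError(
                f"spikes.csv: neuron_id {nid!r} not declared in session.json"
            )
        ts = group["timestamp"].to_numpy(dtype=float)
        if np.any(np.diff(ts) < 0):
            bad = int(group.index[np.flatnonzero(np.diff(ts) < 0)[0] + 1])
            raise ValidationError(
                f"spikes.csv row {bad}: timestamps not sorted for {nid!r}"
            )
        info = declared[str(nid)]
        trains.append(
            SpikeTrain(
                neuron_id=str(nid),
                timestamps=ts,
                region=info.get("region", "STN"),
                unit_grade=info.get("unit_grade", "single"),
            )
        )
    # declared neurons with zero spikes still get an (empty) train
    for nid, info in declared.items():
        if not any(tr.neuron_id == nid for tr in trains):
            trains.append(
                SpikeTrain(
                    neuron_id=nid,
                    timestamps=np.empty(0),
                    region=info.get("region", "STN"),
                    unit_grade=info.get("unit_grade", "single"),
                )
            )

    art = pd.read_csv(_require(path / "artifacts.csv"))
    if len(art):
        bad = art.index[art["end"] <= art["start"]]
        if len(bad):
            raise ValidationError(
                f"artifacts.csv row {int(bad[0])}: end must exceed start"
            )
        epochs = art[["start", "end"]].to_numpy(dtype=float)
    else:
        epochs = np.empty((0, 2))
    return SessionData(
        trials=trials, spike_trains=trains, artifact_epochs=epochs, meta=meta
    )


def find_sessions(root: str | Path) -> list[Path]:
    """Session directories under ``root`` (or ``root`` itself if a bundle)."""
    root = Path(root)
    if (root / "session.json").exists():
        return [root]
    found = sorted(p.parent for p in root.glob("*/session.json"))
    if not found:
        raise ValidationError(f"no session bundles under {root}")
    return found
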