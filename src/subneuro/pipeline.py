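"""End-to-end orchestration: session -> per-neuron inputs -> cohort results.

``prepare_neuron`` turns one neuron's spike train plus the labeled trial
table into the per-analysis inputs (counts, mean rates, drift-corrected and
stimulus-aligned rate matrices), applying artifact-based trial rejection and
the eligibility gates. ``analyze_cohort`` runs the four selectivity analyses
per neuron, the population permutation nulls, region-proportion and overlap
tests, and the latency-mixture fits, and records every exclusion with a
machine-readable reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .behavior import HIT, MISS, apply_qc, behavior_summary, label_outcomes
from .config import ArtifactConfig, NeuronProfile, ObserverModel, TaskConfig
from .errors import ValidationError
from .mixture import MixtureFit, fit_two_gaussian_mixture, significance_trace
from .rates import RateMatrix, catch_drift_correct, epoch_spikes, kernel_rate
from .selectivity import (
    MIN_TRIALS,
    SCAN_WINDOW_MS,
    PopulationResult,
    SelectivityResult,
    cue_selectivity,
    overlap_test,
    perception_selectivity,
    population_count_test,
    proportion_difference_test,
    sensory_selectivity,
    task_selectivity,
)
from .session_io import SessionData, write_session
from .synth import SpikeTrain, SyntheticSession, simulate_session

log = logging.getLogger("subneuro")

ANALYSES = ("cue", "task", "sensory", "perception")

__all__ = [
    "NeuronRecord",
    "CohortResult",
    "prepare_neuron",
    "analyze_neuron",
    "analyze_cohort",
    "sample_profile",
    "simulate_cohort",
    "run_pipeline",
]


@dataclass
class NeuronRecord:
    neuron_id: str
    session_id: str
    region: str
    results: dict[str, SelectivityResult]
    inputs: dict[str, Any] = field(repr=False, default_factory=dict)


@dataclass
class CohortResult:
    neurons: list[NeuronRecord]
    population: dict[str, PopulationResult]
    proportion_p: dict[str, float]
    overlap_p: dict[str, float]
    mixtures: dict[str, MixtureFit | None]
    behavior: pd.DataFrame  # per-session summary
    latency: dict[str, dict[str, float]]

    def selectivity_table(self) -> pd.DataFrame:
        rows = []
        for rec in self.neurons:
            row: dict[str, Any] = {
                "neuron_id": rec.neuron_id,
                "session_id": rec.session_id,
                "region": rec.region,
            }
            for name, res in rec.results.items():
                row[f"{name}_eligible"] = res.eligible
                row[f"{name}_reason"] = res.reason
                row[f"{name}_flag"] = res.flag
                row[f"{name}_p"] = res.p
                row[f"{name}_direction"] = res.direction
                if res.cluster is not None:
                    row[f"{name}_cluster_start_ms"] = res.cluster.start_ms
                    row[f"{name}_cluster_end_ms"] = res.cluster.end_ms
            rows.append(row)
        return pd.DataFrame(rows)


def _counts(timestamps: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    lo = np.searchsorted(timestamps, starts)
    hi = np.searchsorted(timestamps, ends)
    return (hi - lo).astype(float)


def prepare_neuron(
    trials: pd.DataFrame,
    train: SpikeTrain,
    artifact_epochs: np.ndarray,
    task: TaskConfig | None = None,
    session_kept: bool = True,
) -> dict[str, Any]:
    """Build the per-analysis inputs for one neuron.

    ``trials`` must be labeled (and QC'd for the perception analysis).
    Returns a dict with keys ``cue``, ``task`` (paired arrays), ``sensory``
    (drift-corrected RateMatrix + scalar baselines, or an exclusion reason),
    ``perception`` (hit/miss RateMatrix pair or reason), and ``exclusions``.
    """
    task = task or TaskConfig()
    if "outcome" not in trials.columns:
        trials = label_outcomes(trials)
    if "qc_pass" not in trials.columns:
        trials = apply_qc(trials)
    ts = train.timestamps
    out: dict[str, Any] = {"exclusions": {}}
    cue_on = trials["cue_onset"].to_numpy(dtype=float)
    cue_off = trials["cue_offset"].to_numpy(dtype=float)
    stim_on = trials["stim_onset"].to_numpy(dtype=float)

    # cue & task analyses: cue-locked epoch covering baseline through the
    # stimulation window; trials with artifact overlap are dropped whole
    span = (-0.5, task.cue_duration + task.post_cue_delay + task.stim_window)
    _, kept, excl = epoch_spikes(ts, cue_on, span, artifact_epochs)
    out["exclusions"]["cue_task"] = excl
    pre = _counts(ts, cue_on[kept] - 0.5, cue_on[kept])
    post = _counts(ts, cue_off[kept], cue_off[kept] + 0.5)
    out["cue"] = (pre, post)
    win_start = cue_off[kept] + task.post_cue_delay
    out["task"] = (
        pre / 0.5,
        _counts(ts, win_start, win_start + task.stim_window) / task.stim_window,
    )

    # sensory analysis: cue-locked rates for stimulus and catch trials, then
    # catch-mean subtraction and realignment to stimulus onset
    is_stim = np.isfinite(stim_on)
    grid = (-0.6, span[1] + 0.5)
    stim_idx = np.flatnonzero(is_stim)
    catch_idx = np.flatnonzero(~is_stim)
    spk_s, kept_s, excl_s = epoch_spikes(
        ts, cue_on[stim_idx], grid, artifact_epochs, trial_ids=stim_idx
    )
    spk_c, kept_c, excl_c = epoch_spikes(
        ts, cue_on[catch_idx], grid, artifact_epochs, trial_ids=catch_idx
    )
    out["exclusions"]["sensory"] = excl_s + excl_c
    if len(kept_s) < MIN_TRIALS:
        out["sensory"] = f"only {len(kept_s)} artifact-free stimulus trials"
    elif len(kept_c) < 1:
        out["sensory"] = "no artifact-free catch trials for drift correction"
    else:
        stim_rates = kernel_rate(spk_s, grid, trial_ids=kept_s, alignment="cue")
        catch_rates = kernel_rate(spk_c, grid, trial_ids=kept_c, alignment="cue")
        onsets_rel = stim_on[kept_s] - cue_on[kept_s]
        corrected = catch_drift_correct(stim_rates, catch_rates, onsets_rel)
        out["sensory"] = corrected

    # perception analysis: stimulus-locked rates on QC-passed hit/miss trials
    if not session_kept:
        out["perception"] = "session failed behavioral eligibility"
    else:
        qc = trials["qc_pass"].to_numpy(dtype=bool)
        outcome = trials["outcome"].to_numpy()
        win = (-0.3, 0.4)
        groups = {}
        for name, label in (("hit", HIT), ("miss", MISS)):
            idx = np.flatnonzero(qc & (outcome == label))
            spk, kept_g, excl_g = epoch_spikes(
                ts, stim_on[idx], win, artifact_epochs, trial_ids=idx
            )
            out["exclusions"][f"perception_{name}"] = excl_g
            groups[name] = kernel_rate(
                spk, win, trial_ids=kept_g, alignment="stimulus"
            )
        out["perception"] = (groups["hit"], groups["miss"])
    return out


def analyze_neuron(
    prep: dict[str, Any],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, SelectivityResult]:
    """Run the four selectivity analyses on prepared inputs."""
    rng = np.random.default_rng(seed)
    results: dict[str, SelectivityResult] = {}
    results["cue"] = cue_selectivity(*prep["cue"])
    results["task"] = task_selectivity(*prep["task"], n_perm=n_perm, seed=rng)
    if isinstance(prep["sensory"], str):
        results["sensory"] = SelectivityResult.ineligible(prep["sensory"])
    else:
        results["sensory"] = sensory_selectivity(prep["sensory"])
    if isinstance(prep["perception"], str):
        results["perception"] = SelectivityResult.ineligible(prep["perception"])
    else:
        results["perception"] = perception_selectivity(*prep["perception"])
    return results


def _scan_mask(time_ms: np.ndarray) -> np.ndarray:
    return (time_ms >= SCAN_WINDOW_MS[0]) & (time_ms < SCAN_WINDOW_MS[1])


def _population_inputs(records: list[NeuronRecord], analysis: str) -> list:
    items = []
    for rec in records:
        if not rec.results[analysis].eligible:
            continue
        prep = rec.inputs
        if analysis in ("cue", "task"):
            items.append(prep[analysis])
        elif analysis == "sensory":
            rm: RateMatrix = prep["sensory"]
            baseline = rm.window_mean(-300, 0)
            mask = _scan_mask(rm.time_ms)
            items.append(rm.rates[:, mask] - baseline[:, None])
        else:
            hit, miss = prep["perception"]
            mask = _scan_mask(hit.time_ms)
            items.append((hit.rates[:, mask], miss.rates[:, mask]))
    return items


def _latency_summary(records: list[NeuronRecord], analysis: str) -> dict[str, float]:
    starts = [
        r.results[analysis].cluster.start_ms
        for r in records
        if r.results[analysis].flag and r.results[analysis].cluster is not None
    ]
    lengths = [
        r.results[analysis].cluster.length_ms
        for r in records
        if r.results[analysis].flag and r.results[analysis].cluster is not None
    ]
    if not starts:
        return {"n": 0}
    starts, lengths = np.array(starts, float), np.array(lengths, float)

    def sem(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    return {
        "n": len(starts),
        "latency_mean_ms": float(starts.mean()),
        "latency_sem_ms": sem(starts),
        "duration_mean_ms": float(lengths.mean()),
        "duration_sem_ms": sem(lengths),
    }


def analyze_cohort(
    sessions: list[SessionData | SyntheticSession],
    seed: int = 0,
    n_perm: int = 1000,
) -> CohortResult:
    """Per-neuron selectivity plus cohort-level inference for a cohort."""
    rng = np.random.default_rng(seed)
    records: list[NeuronRecord] = []
    behavior_rows = []
    for s_idx, sess in enumerate(sessions):
        if isinstance(sess, SyntheticSession):
            trials, trains, artifacts = sess.trials, sess.spike_trains, sess.artifact_epochs
            task = sess.task
            session_id = f"session_{s_idx:03d}"
            diagnosis = "synthetic"
        else:
            trials, trains, artifacts = sess.trials, sess.spike_trains, sess.artifact_epochs
            task = sess.task
            session_id = sess.meta.get("participant", f"session_{s_idx:03d}")
            diagnosis = sess.meta.get("diagnosis", "unknown")
        trials = apply_qc(label_outcomes(trials))
        summary = behavior_summary(trials)
        behavior_rows.append(
            {
                "session_id": session_id,
                "diagnosis": diagnosis,
                "n_hit": summary.n_hit,
                "n_miss": summary.n_miss,
                "n_cr": summary.n_cr,
                "n_fa": summary.n_fa,
                "n_hit_qc": summary.n_hit_qc,
                "n_miss_qc": summary.n_miss_qc,
                "hit_rate": summary.hit_rate,
                "fa_rate": summary.fa_rate,
                "kept_session": summary.kept_session,
            }
        )
        if not summary.kept_session:
            log.info("%s: failed behavioral eligibility", session_id)
        for train in trains:
            prep = prepare_neuron(
                trials, train, artifacts, task, session_kept=summary.kept_session
            )
            results = analyze_neuron(prep, n_perm=n_perm, seed=rng)
            records.append(
                NeuronRecord(
                    neuron_id=f"{session_id}/{train.neuron_id}",
                    session_id=session_id,
                    region=train.region,
                    results=results,
                    inputs=prep,
                )
            )

    population: dict[str, PopulationResult] = {}
    for analysis in ANALYSES:
        items = _population_inputs(records, analysis)
        if len(items) >= 2:
            population[analysis] = population_count_test(
                items, analysis, n_perm=n_perm, seed=rng
            )

    proportion_p: dict[str, float] = {}
    regions = np.array([r.region for r in records])
    if len(np.unique(regions)) == 2:
        for analysis in ANALYSES:
            eligible = np.array([r.results[analysis].eligible for r in records])
            flags = np.array([r.results[analysis].flag for r in records])
            if eligible.sum() >= 2 and len(np.unique(regions[eligible])) == 2:
                proportion_p[analysis] = proportion_difference_test(
                    flags[eligible], regions[eligible], n_perm=n_perm, seed=rng
                )

    overlap_p: dict[str, float] = {}
    for a, b in (("cue", "task"), ("task", "perception"), ("sensory", "perception")):
        both = np.array(
            [r.results[a].eligible and r.results[b].eligible for r in records]
        )
        if both.sum() >= 2:
            fa = np.array([r.results[a].flag for r in records])[both]
            fb = np.array([r.results[b].flag for r in records])[both]
            overlap_p[f"{a}&{b}"] = overlap_test(fa, fb, n_perm=n_perm, seed=rng)

    mixtures: dict[str, MixtureFit | None] = {}
    latency: dict[str, dict[str, float]] = {}
    for analysis in ("sensory", "perception"):
        clusters = [
            r.results[analysis].cluster
            for r in records
            if r.results[analysis].flag
        ]
        latency[analysis] = _latency_summary(records, analysis)
        trace = significance_trace(clusters)
        mixtures[analysis] = (
            fit_two_gaussian_mixture(trace, seed=rng) if trace.counts.any() else None
        )

    return CohortResult(
        neurons=records,
        population=population,
        proportion_p=proportion_p,
        overlap_p=overlap_p,
        mixtures=mixtures,
        behavior=pd.DataFrame(behavior_rows),
        latency=latency,
    )


# ---------------------------------------------------------------------------
# cohort simulation


def sample_profile(
    rng: np.random.Generator,
    prevalence: dict[str, float] | None = None,
    suppression_prob: float = 0.75,
) -> NeuronProfile:
    """Draw one neuron's ground truth for a study-scale cohort.

    Effect prevalences default to the ~20% range seen for each analysis in
    recordings of this kind; effects are predominantly suppressive, and
    sensory/perception latencies are drawn from an early (~150 ms) or late
    (~320 ms) mode.
    """
    prevalence = prevalence or {
        "cue": 0.18,
        "task": 0.20,
        "sensory": 0.22,
        "perception": 0.23,
    }

    def gain() -> float:
        if rng.random() < suppression_prob:
            return float(rng.uniform(0.25, 0.5))
        return float(rng.uniform(1.8, 2.5))

    def latency() -> float:
        if rng.random() < 0.6:
            return float(np.clip(rng.normal(0.150, 0.030), 0.050, 0.240))
        return float(np.clip(rng.normal(0.320, 0.030), 0.250, 0.380))

    kw: dict[str, float] = {
        "baseline_rate": float(np.clip(rng.lognormal(np.log(20.0), 0.35), 6.0, 60.0))
    }
    if rng.random() < prevalence["cue"]:
        kw["cue_gain"] = gain()
    if rng.random() < prevalence["task"]:
        kw["task_gain"] = gain()
    if rng.random() < prevalence["sensory"]:
        kw.update(
            sensory_gain=gain(),
            sensory_latency=latency(),
            sensory_duration=float(np.clip(rng.normal(0.130, 0.020), 0.100, 0.200)),
        )
    if rng.random() < prevalence["perception"]:
        kw.update(
            perception_gain=gain(),
            perception_latency=latency(),
            perception_duration=float(np.clip(rng.normal(0.120, 0.015), 0.100, 0.180)),
        )
    return NeuronProfile(**kw)


def simulate_cohort(
    n_sessions: int = 48,
    seed: int = 0,
    task: TaskConfig | None = None,
    observer: ObserverModel | None = None,
    artifacts: ArtifactConfig | None = None,
    low_quality_fraction: float = 0.25,
    prevalence: dict[str, float] | None = None,
    stn_fraction: float = 0.5,
    n_neurons: int | None = None,
) -> list[SyntheticSession]:
    """Simulate a cohort of sessions with mixed behavior quality.

    One neuron per session by default; if ``n_neurons`` exceeds
    ``n_sessions`` the surplus neurons are added to the earliest sessions
    (as when two units are isolated on one electrode pass).
    """
    task = task or TaskConfig()
    observer = observer or ObserverModel()
    n_neurons = n_neurons or n_sessions
    if n_neurons < n_sessions:
        raise ValidationError("n_neurons must be >= n_sessions")
    rng = np.random.default_rng(seed)
    session_seeds = rng.integers(0, 2**31 - 1, size=n_sessions)
    sessions = []
    extra = n_neurons - n_sessions
    for i in range(n_sessions):
        obs = observer
        if rng.random() < low_quality_fraction:
            obs = ObserverModel(
                threshold=observer.threshold,
                slope=observer.slope,
                lapse_rate=observer.lapse_rate,
                false_alarm_rate=observer.false_alarm_rate,
                dropout_prob=0.2,
                dropout_len=30,
            )
        n_here = 2 if i < extra else 1
        profiles = [sample_profile(rng, prevalence) for _ in range(n_here)]
        region = "STN" if rng.random() < stn_fraction else "thalamus"
        sessions.append(
            simulate_session(
                profiles,
                seed=int(session_seeds[i]),
                task=task,
                observer=obs,
                artifacts=artifacts,
                region=region,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# filesystem pipeline


def _mixture_dict(fit: MixtureFit | None) -> dict[str, Any] | None:
    if fit is None:
        return None
    return {
        "weights": list(fit.weights),
        "means_ms": list(fit.means_ms),
        "sds_ms": list(fit.sds_ms),
        "mse": fit.mse,
        "mse_1c": fit.mse_1c,
        "mse_ratio_1c": fit.mse_ratio_1c,
        "bimodal": fit.bimodal,
        "n_restarts": fit.n_restarts,
    }


def write_cohort_outputs(result: CohortResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.selectivity_table().to_csv(out / "selectivity.csv", index=False)
    result.behavior.to_csv(out / "behavior_summary.csv", index=False)
    pop = {
        name: {
            "observed_count": r.observed_count,
            "n_total": r.n_total,
            "p": r.p,
            "mode": r.mode,
            "null_mean": r.null_mean,
        }
        for name, r in result.population.items()
    }
    payload = {
        "population": pop,
        "proportion_p": result.proportion_p,
        "overlap_p": result.overlap_p,
        "latency": result.latency,
    }
    (out / "population.json").write_text(json.dumps(payload, indent=2))
    (out / "mixture.json").write_text(
        json.dumps(
            {k: _mixture_dict(v) for k, v in result.mixtures.items()}, indent=2
        )
    )


def plot_significance_traces(result: CohortResult, path: str | Path) -> None:
    """Render the per-ms counts of significant neurons (sensory/perception)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    colors = {"sensory": "tab:green", "perception": "tab:red"}
    for analysis in ("sensory", "perception"):
        clusters = [
            r.results[analysis].cluster
            for r in result.neurons
            if r.results[analysis].flag
        ]
        trace = significance_trace(clusters)
        ax.plot(trace.time_ms, trace.counts, label=analysis, color=colors[analysis])
        fit = result.mixtures.get(analysis)
        if fit is not None and fit.bimodal:
            for m in fit.means_ms:
                ax.axvline(m, color=colors[analysis], ls="--", alpha=0.5)
    ax.set_xlabel("time after stimulus onset (ms)")
    ax.set_ylabel("neurons with a significant effect")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: dict[str, Any], seed: int, out_dir: str | Path) -> CohortResult:
    """simulate -> qc -> analyze -> report, writing a results directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = simulate_cohort(
        n_sessions=int(config.get("n_sessions", 48)),
        seed=seed,
        task=config.get("task"),
        observer=config.get("observer"),
        artifacts=config.get("artifacts"),
        low_quality_fraction=float(config.get("low_quality_fraction", 0.25)),
        prevalence=config.get("prevalence"),
    )
    sess_dir = out / "sessions"
    for i, sess in enumerate(sessions):
        write_session(sess, sess_dir / f"session_{i:03d}")
    analysis_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    result = analyze_cohort(
        sessions, seed=analysis_seed, n_perm=int(config.get("n_perm", 1000))
    )
    write_cohort_outputs(result, out)
    plot_significance_traces(result, out / "significance_trace.png")
    return result
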