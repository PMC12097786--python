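"""Epoching, Gaussian-kernel firing-rate estimation, bootstrap SEM, and
catch-trial drift correction.

Rates are estimated as sums of unit-mass Gaussian kernels (SD 40 ms) on a
1-ms grid, in Hz. Kernels are truncated at +/-4 SD and renormalized so each
spike carries exactly unit mass; epochs are padded by 4 SD of raw spikes so
in-window estimates carry no edge bias. Time is seconds in storage and
milliseconds on analysis grids; windows are half-open ``[start, end)``.

Slow within-trial drifts common to catch and stimulus trials are removed by
subtracting the mean cue-locked catch-trial trace from every stimulus-present
trial in cue-locked time before realigning to stimulus onset; corrected
rates may be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "RateMatrix",
    "epoch_spikes",
    "kernel_rate",
    "bootstrap_sem",
    "catch_drift_correct",
]

KERNEL_SD = 0.040  # seconds
KERNEL_SUPPORT_SD = 4.0
_STEP = 0.001  # 1-ms grid


@dataclass
class RateMatrix:
    """Trials x time matrix of kernel-smoothed firing rates (Hz).

    ``time_ms`` is an integer 1-ms grid relative to the alignment event;
    ``excluded`` lists (trial_id, reason) pairs for trials left out.
    """

    alignment: str  # "cue" | "stimulus"
    time_ms: np.ndarray
    rates: np.ndarray
    trial_ids: np.ndarray
    excluded: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms)
        self.rates = np.asarray(self.rates, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.rates.ndim != 2 or self.rates.shape[1] != len(self.time_ms):
            raise ValidationError("rates must be trials x len(time_ms)")
        if len(self.trial_ids) != self.rates.shape[0]:
            raise ValidationError("one trial_id per rate row required")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    def column(self, t_ms: int) -> np.ndarray:
        idx = int(np.searchsorted(self.time_ms, t_ms))
        if idx >= len(self.time_ms) or self.time_ms[idx] != t_ms:
            raise ValidationError(f"time {t_ms} ms not on grid")
        return self.rates[:, idx]

    def window_mean(self, start_ms: int, end_ms: int) -> np.ndarray:
        """Per-trial mean rate over half-open [start_ms, end_ms)."""
        mask = (self.time_ms >= start_ms) & (self.time_ms < end_ms)
        if not mask.any():
            raise ValidationError(f"window [{start_ms}, {end_ms}) off the grid")
        return self.rates[:, mask].mean(axis=1)


def _overlaps(a0: float, a1: float, epochs: np.ndarray) -> bool:
    if len(epochs) == 0:
        return False
    return bool(np.any((epochs[:, 0] < a1) & (epochs[:, 1] > a0)))


def epoch_spikes(
    timestamps: np.ndarray,
    events: np.ndarray,
    window: tuple[float, float],
    artifact_epochs: np.ndarray | None = None,
    trial_ids: np.ndarray | None = None,
    pad: float = KERNEL_SUPPORT_SD * KERNEL_SD,
) -> tuple[list[np.ndarray], np.ndarray, list[tuple[int, str]]]:
    """Cut per-trial spike epochs aligned to an event.

    Returns ``(spikes, kept_ids, excluded)``: relative spike times per kept
    trial (including ``pad`` seconds beyond each side, for unbiased kernel
    estimates at the window edges), the kept trial ids, and the exclusion
    list. A trial is excluded when its alignment event is absent (NaN, e.g.
    stimulus alignment on a catch trial) or its window overlaps an artifact
    epoch.
    """
    pre, post = window
    if not pre < post:
        raise ValidationError(f"window must satisfy pre < post, got {window}")
    timestamps = np.asarray(timestamps, dtype=float)
    events = np.asarray(events, dtype=float)
    artifact_epochs = (
        np.empty((0, 2)) if artifact_epochs is None else np.asarray(artifact_epochs)
    )
    if trial_ids is None:
        trial_ids = np.arange(len(events))

    spikes: list[np.ndarray] = []
    kept: list[int] = []
    excluded: list[tuple[int, str]] = []
    for tid, ev in zip(trial_ids, events):
        if not np.isfinite(ev):
            excluded.append((int(tid), "no_alignment_event"))
            continue
        if _overlaps(ev + pre, ev + post, artifact_epochs):
            excluded.append((int(tid), "artifact_overlap"))
            continue
        lo, hi = ev + pre - pad, ev + post + pad
        sel = timestamps[(timestamps >= lo) & (timestamps < hi)] - ev
        spikes.append(sel)
        kept.append(int(tid))
    return spikes, np.asarray(kept, dtype=int), excluded


def kernel_rate(
    epoched_spikes: list[np.ndarray],
    window: tuple[float, float],
    trial_ids: np.ndarray | None = None,
    alignment: str = "cue",
    sd: float = KERNEL_SD,
    excluded: list[tuple[int, str]] | None = None,
) -> RateMatrix:
    """Gaussian-kernel rate estimate on a 1-ms grid.

    Each trial's rate trace is the sum of unit-mass Gaussians (SD ``sd``)
    centered on its spikes, truncated at +/-4 SD and renormalized, so the
    integral of the trace over the spikes' support equals the spike count.
    """
    if not sd > 0:
        raise ValidationError("kernel sd must be > 0")
    pre, post = window
    t_ms = np.arange(int(round(pre * 1000)), int(round(post * 1000)))
    t_s = t_ms * _STEP
    trunc = KERNEL_SUPPORT_SD * sd
    # mass inside +/-4 SD; dividing by it restores exact unit mass per spike
    from scipy.special import erf

    mass = erf(KERNEL_SUPPORT_SD / np.sqrt(2))
    norm = 1.0 / (np.sqrt(2 * np.pi) * sd * mass)

    if trial_ids is None:
        trial_ids = np.arange(len(epoched_spikes))
    rates = np.zeros((len(epoched_spikes), len(t_ms)))
    for i, spk in enumerate(epoched_spikes):
        spk = np.asarray(spk, dtype=float)
        if len(spk) == 0:
            continue
        d = t_s[None, :] - spk[:, None]
        k = np.where(np.abs(d) <= trunc, np.exp(-0.5 * (d / sd) ** 2), 0.0)
        rates[i] = norm * k.sum(axis=0)
    return RateMatrix(
        alignment=alignment,
        time_ms=t_ms,
        rates=rates,
        trial_ids=trial_ids,
        excluded=list(excluded or []),
    )


def bootstrap_sem(
    rates: RateMatrix | np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Bootstrap standard error of the trial-mean rate at each time point.

    Trials are resampled with replacement ``n_boot`` times; the SEM trace is
    the standard deviation of the resampled means.
    """
    x = rates.rates if isinstance(rates, RateMatrix) else np.asarray(rates, float)
    n = x.shape[0]
    if n < 2:
        raise ValidationError("bootstrap SEM needs at least two trials")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = x[idx].mean(axis=1)
    return means.std(axis=0, ddof=1)


def catch_drift_correct(
    stim_rates: RateMatrix,
    catch_rates: RateMatrix,
    stim_onsets: np.ndarray,
    out_window: tuple[float, float] = (-0.3, 0.4),
    min_catch_warn: int = 5,
) -> RateMatrix:
    """Remove cue-locked drift using catch trials, then realign to stimulus.

    The mean cue-locked catch-trial trace is subtracted pointwise from every
    cue-locked stimulus-present trial; each residual trace is then resampled
    onto a stimulus-locked grid using that trial's stimulus onset (seconds,
    relative to the cue alignment zero). Corrected rates may be negative —
    they are residuals, not rates.
    """
    if catch_rates.n_trials < 1:
        raise ValidationError("drift correction needs at least one catch trial")
    if catch_rates.n_trials < min_catch_warn:
        warnings.warn(
            f"only {catch_rates.n_trials} catch trials available for drift "
            "correction; the catch mean will be noisy",
            stacklevel=2,
        )
    if not np.array_equal(stim_rates.time_ms, catch_rates.time_ms):
        raise ValidationError("stimulus and catch matrices must share a grid")
    stim_onsets = np.asarray(stim_onsets, dtype=float)
    if len(stim_onsets) != stim_rates.n_trials:
        raise ValidationError("one stimulus onset per stimulus trial required")

    resid = stim_rates.rates - catch_rates.rates.mean(axis=0)
    out_ms = np.arange(
        int(round(out_window[0] * 1000)), int(round(out_window[1] * 1000))
    )
    t0 = int(stim_rates.time_ms[0])
    corrected = np.empty((stim_rates.n_trials, len(out_ms)))
    for i, onset in enumerate(stim_onsets):
        shift = int(round(onset * 1000))
        idx = out_ms + shift - t0
        if idx[0] < 0 or idx[-1] >= resid.shape[1]:
            raise ValidationError(
                f"trial {stim_rates.trial_ids[i]}: cue-locked grid does not "
                "cover the requested stimulus-locked window"
            )
        corrected[i] = resid[i, idx]
    return RateMatrix(
        alignment="stimulus",
        time_ms=out_ms,
        rates=corrected,
        trial_ids=stim_rates.trial_ids,
        excluded=list(stim_rates.excluded),
    )
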