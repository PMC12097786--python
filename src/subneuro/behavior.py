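"""Behavioral quality control and permutation tests.

Trials are labeled hit / miss / correct_rejection / false_alarm from the
stimulus flag and the verbal report. Because intraoperative vigilance
fluctuates, analysis keeps only stretches of balanced performance: the
trial-by-trial hit rate is estimated with an 11-trial sliding window over
stimulus trials (edges mirrored), trials outside the open (25%, 75%) band
are dropped, and a session survives only if at least 10 hits and 10 misses
remain.

Covariate permutation tests check that hits and misses do not differ in
stimulus amplitude or onset; the diagnosis-group comparison uses the
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "HIT",
    "MISS",
    "CR",
    "FA",
    "label_outcomes",
    "sliding_hit_rate",
    "filter_trials",
    "session_eligibility",
    "apply_qc",
    "behavior_summary",
    "covariate_permutation_test",
    "group_rate_comparison",
    "BehaviorSummary",
    "PermutationResult",
]

HIT = "hit"
MISS = "miss"
CR = "correct_rejection"
FA = "false_alarm"

# Exhaustive enumeration is used instead of Monte-Carlo sampling whenever
# the permutation space is at most this large.
EXACT_LIMIT = 1024


@dataclass(frozen=True)
class BehaviorSummary:
    n_hit: int
    n_miss: int
    n_cr: int
    n_fa: int
    hit_rate: float
    fa_rate: float
    kept_session: bool
    n_hit_qc: int = 0  # hits surviving the sliding hit-rate filter
    n_miss_qc: int = 0


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_two: float
    p_greater: float
    p_less: float
    n_perm: int
    method: str  # "exact" | "mc"


def label_outcomes(trials: pd.DataFrame) -> pd.DataFrame:
    """Derive the four-way outcome label from stimulus presence and report."""
    if "report" not in trials.columns or trials["report"].isna().any():
        raise ValidationError("every trial needs a report before labeling outcomes")
    bad = trials["report"].isin(["yes", "no"]) == False  # noqa: E712
    if bad.any():
        row = int(trials.index[bad][0])
        raise ValidationError(f"trial {row}: report must be 'yes' or 'no'")
    has_stim = np.isfinite(trials["stim_onset"].to_numpy(dtype=float))
    yes = (trials["report"] == "yes").to_numpy()
    outcome = np.where(
        has_stim, np.where(yes, HIT, MISS), np.where(yes, FA, CR)
    )
    out = trials.copy()
    out["outcome"] = outcome
    return out


def sliding_hit_rate(outcomes: np.ndarray, window: int = 11) -> np.ndarray:
    """Sliding hit rate over ordered stimulus-trial outcomes.

    ``outcomes`` is a 0/1 (or boolean) array over stimulus trials only. The
    sequence is extended by mirror reflection (edge element not repeated) so
    that the trace has the same length as the input.
    """
    x = np.asarray(outcomes, dtype=float)
    if window % 2 != 1 or window < 1:
        raise ValidationError(f"window must be odd and >= 1, got {window}")
    if len(x) < window:
        raise ValidationError(
            f"need at least {window} stimulus trials, got {len(x)}"
        )
    half = (window - 1) // 2
    padded = np.pad(x, half, mode="reflect") if half else x
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def filter_trials(
    trace: np.ndarray, lower: float = 0.25, upper: float = 0.75
) -> np.ndarray:
    """Keep trials whose local hit rate lies strictly inside (lower, upper)."""
    t = np.asarray(trace, dtype=float)
    return (t > lower) & (t < upper)


def session_eligibility(
    outcomes: np.ndarray, qc_mask: np.ndarray, min_each: int = 10
) -> bool:
    """A session is kept iff >= 10 hits AND >= 10 misses survive the filter."""
    outcomes = np.asarray(outcomes)
    qc_mask = np.asarray(qc_mask, dtype=bool)
    n_hit = int(np.sum(qc_mask & (outcomes == HIT)))
    n_miss = int(np.sum(qc_mask & (outcomes == MISS)))
    return n_hit >= min_each and n_miss >= min_each


def apply_qc(
    trials: pd.DataFrame, window: int = 11, lower: float = 0.25, upper: float = 0.75
) -> pd.DataFrame:
    """Attach ``local_hit_rate`` and ``qc_pass`` columns to a labeled table.

    The window slides over stimulus trials only (catch trials carry no
    hit/miss information); catch trials always pass, since the filter exists
    to balance the hit/miss contrast. The trace is computed once on the
    original ordering — re-filtering kept trials is a no-op by construction.
    """
    if "outcome" not in trials.columns:
        trials = label_outcomes(trials)
    stim = trials["outcome"].isin([HIT, MISS]).to_numpy()
    out = trials.copy()
    out["local_hit_rate"] = np.nan
    out["qc_pass"] = True
    trace = sliding_hit_rate((trials.loc[stim, "outcome"] == HIT).to_numpy(), window)
    out.loc[stim, "local_hit_rate"] = trace
    out.loc[stim, "qc_pass"] = filter_trials(trace, lower, upper)
    return out


def behavior_summary(trials: pd.DataFrame, min_each: int = 10) -> BehaviorSummary:
    """Outcome counts, rates, and the session-eligibility flag.

    Counts are raw; eligibility is evaluated on QC-passed trials (the table
    must already carry ``qc_pass``; otherwise QC is applied with defaults).
    """
    if "qc_pass" not in trials.columns:
        trials = apply_qc(trials)
    outcome = trials["outcome"].to_numpy()
    counts = {k: int(np.sum(outcome == k)) for k in (HIT, MISS, CR, FA)}
    n_stim = counts[HIT] + counts[MISS]
    n_catch = counts[CR] + counts[FA]
    qc = trials["qc_pass"].to_numpy(dtype=bool)
    kept = session_eligibility(outcome, qc, min_each)
    return BehaviorSummary(
        n_hit=counts[HIT],
        n_miss=counts[MISS],
        n_cr=counts[CR],
        n_fa=counts[FA],
        hit_rate=counts[HIT] / n_stim if n_stim else np.nan,
        fa_rate=counts[FA] / n_catch if n_catch else np.nan,
        kept_session=kept,
        n_hit_qc=int(np.sum(qc & (outcome == HIT))),
        n_miss_qc=int(np.sum(qc & (outcome == MISS))),
    )


def covariate_permutation_test(
    values_hit: np.ndarray,
    values_miss: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation test for a difference in group means (hit vs miss).

    Used for stimulus amplitude and stimulus onset. When the number of
    distinct label assignments is small (<= 1024) the null is enumerated
    exhaustively and p-values are exact proportions; otherwise ``n_perm``
    random label shuffles are drawn and the add-one correction
    ``p = (1 + #{null >= obs}) / (1 + n_perm)`` is applied.
    """
    x = np.asarray(values_hit, dtype=float)
    y = np.asarray(values_miss, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    obs = x.mean() - y.mean()

    if comb(n, nx) <= EXACT_LIMIT:
        diffs = np.array(
            [
                pooled[list(idx)].mean()
                - np.delete(pooled, list(idx)).mean()
                for idx in combinations(range(n), nx)
            ]
        )
        p_two = float(np.mean(np.abs(diffs) >= abs(obs) - 1e-12))
        p_greater = float(np.mean(diffs >= obs - 1e-12))
        p_less = float(np.mean(diffs <= obs + 1e-12))
        return PermutationResult(obs, p_two, p_greater, p_less, len(diffs), "exact")

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = perm[:nx].mean() - perm[nx:].mean()
    p_two = (1 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (1 + n_perm)
    p_greater = (1 + np.sum(null >= obs - 1e-12)) / (1 + n_perm)
    p_less = (1 + np.sum(null <= obs + 1e-12)) / (1 + n_perm)
    return PermutationResult(obs, p_two, p_greater, p_less, n_perm, "mc")


def group_rate_comparison(
    rates_a: np.ndarray, rates_b: np.ndarray
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of per-participant rates between groups.

    Returns ``(W, p)`` where W is the rank sum of the first group. Exact
    p-values are used for small samples (scipy's default switching rule).
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least two sessions per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    w = float(res.statistic + len(a) * (len(a) + 1) / 2)
    return w, float(res.pvalue)
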