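"""Identification of cue-, task-, sensory-, and perception-selective neurons.

Four analyses, each gated on a minimum of 20 usable trials per condition:

* cue: exact two-tailed sign test on per-trial spike counts, 500 ms pre-cue
  baseline vs 500 ms after cue offset (ties dropped).
* task: paired sign-flip permutation test on per-trial mean rates, baseline
  vs the 2-s stimulation window (rates in Hz keep the unequal durations
  comparable).
* sensory: drift-corrected stimulus-aligned rates scanned against each
  trial's scalar 300-ms pre-stimulus baseline with a paired signed-rank
  test at every 1-ms step in the first 400 ms.
* perception: hit vs miss rates scanned with an unpaired rank-sum test over
  the same window (additionally requires >= 10 hits and >= 10 misses).

For the scans, a neuron is selective when a contiguous run of pointwise
significance (alpha = 0.05, two-sided) lasts strictly longer than 80 ms —
twice the smoothing-kernel SD; of multiple such runs only the longest
(earliest on ties) is kept. Population-level inference re-runs the full
per-neuron pipeline under sign-flipped differences (paired analyses) or
shuffled condition labels (unpaired) 1000 times and compares the observed
count of selective neurons to the resulting null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats as sstats

from .errors import ValidationError
from .rates import RateMatrix
from .stats import (
    all_assignments,
    all_sign_flips,
    find_runs,
    has_run,
    perm_pvalue,
    ranksum_assign_p,
    ranksum_p,
    signrank_flip_p,
    signrank_p,
)

__all__ = [
    "ClusterResult",
    "SelectivityResult",
    "PopulationResult",
    "cue_selectivity",
    "task_selectivity",
    "cluster_scan",
    "sensory_selectivity",
    "perception_selectivity",
    "population_count_test",
    "proportion_difference_test",
    "overlap_test",
    "covariate_control_scan",
]

ALPHA = 0.05
MIN_TRIALS = 20
MIN_CLUSTER_MS = 80  # a cluster must be strictly longer than this
SCAN_WINDOW_MS = (0, 400)
EXACT_LIMIT = 1024

INCREASE = "increase"
DECREASE = "decrease"


@dataclass(frozen=True)
class ClusterResult:
    """Longest surviving run of pointwise significance (ms, half-open)."""

    start_ms: int
    end_ms: int
    sign: str  # "increase"/"decrease" (paired) or "A>B"/"A<B" (unpaired)
    pointwise_p: np.ndarray = field(repr=False, default=None)

    @property
    def length_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class SelectivityResult:
    flag: bool
    p: float | None
    direction: str | None
    cluster: ClusterResult | None
    eligible: bool
    reason: str | None = None

    @classmethod
    def ineligible(cls, reason: str) -> "SelectivityResult":
        return cls(False, None, None, None, False, reason)


@dataclass
class PopulationResult:
    observed_count: int
    n_total: int
    null_counts: np.ndarray  # sampled null counts (MC) or exact count pmf
    p: float
    mode: str  # "sign_flip" | "label_shuffle"
    exact: bool = False

    @property
    def null_mean(self) -> float:
        if self.exact:
            return float(np.sum(np.arange(len(self.null_counts)) * self.null_counts))
        return float(np.mean(self.null_counts))


# ---------------------------------------------------------------------------
# per-neuron window tests


def cue_selectivity(
    counts_pre: np.ndarray,
    counts_post: np.ndarray,
    min_trials: int = MIN_TRIALS,
    alpha: float = ALPHA,
) -> SelectivityResult:
    """Exact two-tailed sign test: spikes after cue offset vs pre-cue."""
    pre = np.asarray(counts_pre, dtype=float)
    post = np.asarray(counts_post, dtype=float)
    if len(pre) != len(post):
        raise ValidationError("pre and post counts must pair per trial")
    if len(pre) < min_trials:
        return SelectivityResult.ineligible(
            f"only {len(pre)} trials (< {min_trials})"
        )
    d = post - pre
    nonzero = d != 0
    n = int(nonzero.sum())
    if n == 0:
        return SelectivityResult(False, 1.0, None, None, True)
    k = int(np.sum(d > 0))
    p = float(sstats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    flag = p < alpha
    direction = (INCREASE if k > n - k else DECREASE) if flag else None
    return SelectivityResult(flag, p, direction, None, True)


def _sign_flip_null(d: np.ndarray, n_perm: int, rng: np.random.Generator):
    """Mean-difference null under sign flips; exact when 2^n is small."""
    n = len(d)
    if 2**n <= EXACT_LIMIT:
        flips = all_sign_flips(n)
        return (flips @ d) / n, "exact"
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    return (signs @ d) / n, "mc"


def task_selectivity(
    rate_baseline: np.ndarray,
    rate_window: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    min_trials: int = MIN_TRIALS,
    alpha: float = ALPHA,
) -> SelectivityResult:
    """Paired sign-flip permutation test on per-trial mean rates (Hz)."""
    base = np.asarray(rate_baseline, dtype=float)
    win = np.asarray(rate_window, dtype=float)
    if len(base) != len(win):
        raise ValidationError("baseline and window rates must pair per trial")
    if len(base) < min_trials:
        return SelectivityResult.ineligible(
            f"only {len(base)} trials (< {min_trials})"
        )
    d = win - base
    obs = float(d.mean())
    null, method = _sign_flip_null(d, n_perm, np.random.default_rng(seed))
    if method == "exact":
        p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
    else:
        p = perm_pvalue(obs, null, mode="abs")
    flag = p < alpha
    direction = (INCREASE if obs > 0 else DECREASE) if flag else None
    return SelectivityResult(flag, p, direction, None, True)


# ---------------------------------------------------------------------------
# cluster scan


def _restrict(time_ms: np.ndarray, window_ms: tuple[int, int]) -> np.ndarray:
    mask = (time_ms >= window_ms[0]) & (time_ms < window_ms[1])
    if not mask.any():
        raise ValidationError(f"scan window {window_ms} off the time grid")
    return mask


def _pick_cluster(
    sig: np.ndarray,
    time_ms: np.ndarray,
    min_len_ms: int,
) -> tuple[int, int] | None:
    runs = [
        (s, e) for s, e in find_runs(sig) if (e - s) > min_len_ms
    ]  # 1-ms grid: samples == ms; strict "> 80 ms"
    if not runs:
        return None
    lengths = [e - s for s, e in runs]
    s, e = runs[int(np.argmax(lengths))]  # earliest longest
    return int(time_ms[s]), int(time_ms[e - 1]) + 1


def cluster_scan(
    rates_a: np.ndarray,
    rates_b_or_baseline: np.ndarray,
    time_ms: np.ndarray,
    test: str = "signrank",
    window_ms: tuple[int, int] = SCAN_WINDOW_MS,
    alpha: float = ALPHA,
    min_len_ms: int = MIN_CLUSTER_MS,
) -> ClusterResult | None:
    """Pointwise scan for a sustained rate difference.

    ``test="signrank"`` compares each time point of ``rates_a`` (trials x T)
    against the per-trial scalar baseline in ``rates_b_or_baseline``
    (paired); ``test="ranksum"`` compares two trial groups (unpaired).
    Returns the longest run of pointwise significance strictly exceeding
    ``min_len_ms``, or None.
    """
    time_ms = np.asarray(time_ms)
    mask = _restrict(time_ms, window_ms)
    a = np.atleast_2d(np.asarray(rates_a, dtype=float))[:, mask]
    t = time_ms[mask]
    if test == "signrank":
        baseline = np.asarray(rates_b_or_baseline, dtype=float)
        if baseline.ndim != 1 or len(baseline) != a.shape[0]:
            raise ValidationError("paired scan needs one scalar baseline per trial")
        diffs = a - baseline[:, None]
        p = signrank_p(diffs)
        mean_diff = diffs.mean(axis=0)
        signs = (INCREASE, DECREASE)
    elif test == "ranksum":
        b = np.atleast_2d(np.asarray(rates_b_or_baseline, dtype=float))[:, mask]
        p = ranksum_p(a, b)
        mean_diff = a.mean(axis=0) - b.mean(axis=0)
        signs = ("A>B", "A<B")
    else:
        raise ValidationError(f"unknown test {test!r}")

    bounds = _pick_cluster(p < alpha, t, min_len_ms)
    if bounds is None:
        return None
    start, end = bounds
    in_cluster = (t >= start) & (t < end)
    sign = signs[0] if mean_diff[in_cluster].mean() > 0 else signs[1]
    return ClusterResult(start, end, sign, pointwise_p=p)


def sensory_selectivity(
    corrected: RateMatrix,
    baseline_window_ms: tuple[int, int] = (-300, 0),
    window_ms: tuple[int, int] = SCAN_WINDOW_MS,
    min_trials: int = MIN_TRIALS,
    alpha: float = ALPHA,
) -> SelectivityResult:
    """Post-stimulus modulation vs the 300-ms pre-stimulus baseline.

    Expects drift-corrected, stimulus-aligned rates (see
    :func:`subneuro.rates.catch_drift_correct`); the baseline is each
    trial's scalar mean over the pre-stimulus window.
    """
    if corrected.n_trials < min_trials:
        return SelectivityResult.ineligible(
            f"only {corrected.n_trials} stimulus trials (< {min_trials})"
        )
    baseline = corrected.window_mean(*baseline_window_ms)
    cluster = cluster_scan(
        corrected.rates,
        baseline,
        corrected.time_ms,
        test="signrank",
        window_ms=window_ms,
        alpha=alpha,
    )
    if cluster is None:
        return SelectivityResult(False, None, None, None, True)
    return SelectivityResult(True, None, cluster.sign, cluster, True)


def perception_selectivity(
    hit_rates: RateMatrix,
    miss_rates: RateMatrix,
    window_ms: tuple[int, int] = SCAN_WINDOW_MS,
    min_each: int = 10,
    min_total: int = MIN_TRIALS,
    alpha: float = ALPHA,
) -> SelectivityResult:
    """Hit-vs-miss rate difference in the first 400 ms post-stimulus."""
    n_hit, n_miss = hit_rates.n_trials, miss_rates.n_trials
    if n_hit < min_each or n_miss < min_each or n_hit + n_miss < min_total:
        return SelectivityResult.ineligible(
            f"{n_hit} hits / {n_miss} misses (need >= {min_each} each, "
            f">= {min_total} total)"
        )
    if not np.array_equal(hit_rates.time_ms, miss_rates.time_ms):
        raise ValidationError("hit and miss matrices must share a time grid")
    cluster = cluster_scan(
        hit_rates.rates,
        miss_rates.rates,
        hit_rates.time_ms,
        test="ranksum",
        window_ms=window_ms,
        alpha=alpha,
    )
    if cluster is None:
        return SelectivityResult(False, None, None, None, True)
    direction = "hit>miss" if cluster.sign == "A>B" else "miss>hit"
    return SelectivityResult(True, None, direction, cluster, True)


# ---------------------------------------------------------------------------
# population-level permutation nulls


def _cluster_flags_paired(
    diffs: np.ndarray,
    flips: np.ndarray,
    alpha: float,
    min_len_ms: int,
) -> np.ndarray:
    p = signrank_flip_p(diffs, flips)
    return has_run(p < alpha, min_len_ms + 1)


def _binom_two_tail_table(n: int) -> np.ndarray:
    """p-value for each k of an exact two-tailed sign test at n trials."""
    return np.array(
        [sstats.binomtest(k, n, 0.5).pvalue for k in range(n + 1)]
    )


def _neuron_flag_vector(
    item,
    analysis: str,
    variants: np.ndarray | None,
    n_perm: int,
    rng: np.random.Generator,
    alpha: float,
    min_len_ms: int,
) -> np.ndarray:
    """Selectivity decisions for one neuron across permutation variants.

    ``variants`` is the full enumeration of that neuron's permutation space
    (sign matrices or assignment rows, identity first) in exact mode, or
    None to draw ``n_perm`` random variants after the identity row.
    """
    if analysis == "cue":
        pre, post = (np.asarray(v, dtype=float) for v in item)
        d = post - pre
        d = d[d != 0]
        n = len(d)
        if n == 0:
            size = 1 if variants is not None else n_perm + 1
            return np.zeros(size, dtype=bool)
        ptab = _binom_two_tail_table(n)
        signs = (
            variants
            if variants is not None
            else np.vstack([np.ones(n), rng.choice((-1.0, 1.0), size=(n_perm, n))])
        )
        k = ((signs * np.sign(d)) > 0).sum(axis=1)
        return ptab[k] < alpha
    if analysis == "task":
        base, win = (np.asarray(v, dtype=float) for v in item)
        d = win - base
        n = len(d)
        inner_null, method = _sign_flip_null(d, n_perm, rng)
        sorted_abs = np.sort(np.abs(inner_null))
        outer = (
            variants
            if variants is not None
            else np.vstack([np.ones(n), rng.choice((-1.0, 1.0), size=(n_perm, n))])
        )
        stats_o = np.abs(outer @ d) / n
        n_ge = len(sorted_abs) - np.searchsorted(
            sorted_abs, stats_o - 1e-12, side="left"
        )
        if method == "exact":
            p_o = n_ge / len(sorted_abs)
        else:
            p_o = (1 + n_ge) / (1 + len(sorted_abs))
        return p_o < alpha
    if analysis == "sensory":
        diffs = np.asarray(item, dtype=float)
        n = diffs.shape[0]
        flips = (
            variants
            if variants is not None
            else np.vstack([np.ones(n), rng.choice((-1.0, 1.0), size=(n_perm, n))])
        )
        return _cluster_flags_paired(diffs, flips, alpha, min_len_ms)
    if analysis == "perception":
        hit, miss = (np.atleast_2d(np.asarray(v, dtype=float)) for v in item)
        pooled = np.vstack([hit, miss])
        n, n_hit = pooled.shape[0], hit.shape[0]
        if variants is not None:
            assign = variants
        else:
            observed_row = np.zeros(n, dtype=bool)
            observed_row[:n_hit] = True
            shuffles = np.array(
                [rng.permutation(observed_row) for _ in range(n_perm)]
            )
            assign = np.vstack([observed_row[None, :], shuffles])
        p = ranksum_assign_p(pooled, assign)
        return has_run(p < alpha, min_len_ms + 1)
    raise ValidationError(f"unknown analysis {analysis!r}")


def _space_size(item, analysis: str) -> int:
    if analysis == "cue":
        pre, post = (np.asarray(v, dtype=float) for v in item)
        n = int(np.sum(post - pre != 0))
        return 2**n
    if analysis == "task":
        return 2 ** len(np.asarray(item[0]))
    if analysis == "sensory":
        return 2 ** np.asarray(item).shape[0]
    hit, miss = (np.atleast_2d(np.asarray(v)) for v in item)
    return comb(hit.shape[0] + miss.shape[0], hit.shape[0])


def _enumerate_variants(item, analysis: str) -> np.ndarray:
    if analysis == "cue":
        pre, post = (np.asarray(v, dtype=float) for v in item)
        d = post - pre
        return all_sign_flips(int(np.sum(d != 0)))
    if analysis in ("task",):
        return all_sign_flips(len(np.asarray(item[0])))
    if analysis == "sensory":
        return all_sign_flips(np.asarray(item).shape[0])
    hit, miss = (np.atleast_2d(np.asarray(v)) for v in item)
    return all_assignments(hit.shape[0] + miss.shape[0], hit.shape[0])


def _poisson_binomial_pmf(qs: list[float]) -> np.ndarray:
    pmf = np.array([1.0])
    for q in qs:
        pmf = np.convolve(pmf, [1.0 - q, q])
    return pmf


def population_count_test(
    neuron_inputs: list,
    analysis: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = ALPHA,
    min_len_ms: int = MIN_CLUSTER_MS,
    exact: bool | None = None,
) -> PopulationResult:
    """Permutation null for the count of selective neurons.

    For every permutation the full per-neuron decision rule is re-run on
    sign-flipped per-trial differences (``analysis`` in cue/task/sensory) or
    shuffled hit/miss labels (perception), and selective neurons are
    re-counted.

    When the joint permutation space is small (product of per-neuron spaces
    <= 1024, or ``exact=True``) each neuron's space is enumerated
    exhaustively; since neurons permute independently, the exact null of the
    count is the Poisson-binomial convolution of per-neuron flag
    probabilities, and p is its upper tail at the observed count. Otherwise
    ``n_perm`` Monte-Carlo permutations are drawn and
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.

    ``neuron_inputs`` holds one entry per eligible neuron:

    * cue: ``(counts_pre, counts_post)``
    * task: ``(rate_baseline, rate_window)``
    * sensory: difference matrix trials x T (corrected rate minus scalar
      baseline), already restricted to the scan window
    * perception: ``(hit_rates, miss_rates)`` matrices restricted likewise
    """
    if len(neuron_inputs) < 2:
        raise ValidationError("population test needs >= 2 eligible neurons")
    rng = np.random.default_rng(seed)
    mode = "label_shuffle" if analysis == "perception" else "sign_flip"

    if exact is None:
        total = 1
        for item in neuron_inputs:
            total *= _space_size(item, analysis)
            if total > EXACT_LIMIT:
                break
        exact = total <= EXACT_LIMIT

    if exact:
        qs, observed = [], 0
        for item in neuron_inputs:
            flags = _neuron_flag_vector(
                item, analysis, _enumerate_variants(item, analysis),
                n_perm, rng, alpha, min_len_ms,
            )
            observed += int(flags[0])  # identity permutation comes first
            qs.append(float(flags.mean()))
        pmf = _poisson_binomial_pmf(qs)
        p = float(pmf[observed:].sum())
        return PopulationResult(observed, len(neuron_inputs), pmf, p, mode, exact=True)

    counts = np.zeros(n_perm + 1, dtype=int)  # slot 0 = observed (identity)
    for item in neuron_inputs:
        counts += _neuron_flag_vector(
            item, analysis, None, n_perm, rng, alpha, min_len_ms
        )
    observed = int(counts[0])
    p = perm_pvalue(observed, counts[1:], mode="ge")
    return PopulationResult(observed, len(neuron_inputs), counts[1:], p, mode)


def proportion_difference_test(
    flags: np.ndarray,
    region_labels: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Permutation p for |proportion(STN) - proportion(thalamus)|."""
    flags = np.asarray(flags, dtype=bool)
    regions = np.asarray(region_labels)
    uniq = np.unique(regions)
    if len(uniq) != 2:
        raise ValidationError(f"need exactly two regions, got {list(uniq)}")
    in_a = regions == uniq[0]
    n_a = int(in_a.sum())

    def stat(mask_a: np.ndarray) -> float:
        return abs(flags[mask_a].mean() - flags[~mask_a].mean())

    obs = stat(in_a)
    if comb(len(flags), n_a) <= EXACT_LIMIT:
        null = np.array([stat(row) for row in all_assignments(len(flags), n_a)])
        return float(np.mean(null >= obs - 1e-12))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stat(rng.permutation(in_a))
    return perm_pvalue(obs, null, mode="ge")


def overlap_test(
    flags_a: np.ndarray,
    flags_b: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Permutation p for the co-selectivity count |A and B|.

    One flag vector is shuffled across the common neuron set; since only
    which positions carry a B flag matters, the exact null enumerates the
    C(n, k_b) distinct placements when that space is small.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("flag vectors must cover the same neuron set")
    obs = int(np.sum(a & b))
    n, k_b = len(b), int(b.sum())
    if comb(n, k_b) <= EXACT_LIMIT:
        null = np.array(
            [int(np.sum(a & row)) for row in all_assignments(n, k_b)]
        )
        return float(np.mean(null >= obs - 1e-12))
    rng = np.random.default_rng(seed)
    null = np.array([int(np.sum(a & rng.permutation(b))) for _ in range(n_perm)])
    return perm_pvalue(obs, null, mode="ge")


def covariate_control_scan(
    rates: RateMatrix,
    values: np.ndarray,
    window_ms: tuple[int, int] = SCAN_WINDOW_MS,
    min_per_group: int = MIN_TRIALS,
    alpha: float = ALPHA,
) -> SelectivityResult:
    """Median-split control contrast (high vs low amplitude, early vs late
    onset): an unpaired cluster scan between the two halves certifies that a
    flagged neuron is not an amplitude or onset artifact."""
    values = np.asarray(values, dtype=float)
    if len(values) != rates.n_trials:
        raise ValidationError("one covariate value per trial required")
    order = np.argsort(values, kind="stable")
    half = len(values) // 2
    low, high = order[:half], order[half:]
    if len(low) < min_per_group or len(high) < min_per_group:
        return SelectivityResult.ineligible(
            f"median split leaves {len(low)}/{len(high)} trials "
            f"(need >= {min_per_group} each)"
        )
    cluster = cluster_scan(
        rates.rates[high],
        rates.rates[low],
        rates.time_ms,
        test="ranksum",
        window_ms=window_ms,
        alpha=alpha,
    )
    if cluster is None:
        return SelectivityResult(False, None, None, None, True)
    direction = "high>low" if cluster.sign == "A>B" else "low>high"
    return SelectivityResult(True, None, direction, cluster, True)
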