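"""Vectorized nonparametric tests and cluster utilities.

The cluster scans need a two-sided test at every 1-ms time point, and the
population-level permutation nulls re-run those scans a thousand times, so
the signed-rank and rank-sum tests are implemented column-wise on whole
trials x time matrices using the normal approximation with exact
first/second moments computed from the realized (tie-averaged) ranks:

* signed rank: under random signs, ``W+ = sum r_i b_i`` with ``b_i ~
  Bernoulli(1/2)``, so ``E[W+] = sum(r)/2`` and ``Var[W+] = sum(r^2)/4``
  exactly, ties included. Zero differences are dropped per column.
* rank sum: under random group assignment the group-A rank sum has the
  finite-population moments of a without-replacement sample of the pooled
  (tie-averaged) ranks.

Because |differences| (hence ranks) are invariant under sign flips, and
pooled ranks are invariant under label shuffles, permutation statistics
reduce to a single matrix product per null: ``W+ = (sum r + S @ (r *
sign(d))) / 2`` for sign-flip matrices ``S`` and ``W_A = L @ R`` for
assignment matrices ``L``.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy import stats as sstats

__all__ = [
    "signrank_p",
    "signrank_flip_p",
    "ranksum_p",
    "ranksum_assign_p",
    "find_runs",
    "longest_run",
    "has_run",
    "all_sign_flips",
    "all_assignments",
    "perm_pvalue",
]


def _masked_ranks(absd: np.ndarray, nonzero: np.ndarray) -> np.ndarray:
    """Tie-averaged ranks of |d| among nonzero entries, per column.

    Zeros are pushed below every nonzero value before ranking, then the
    per-column zero count is subtracted, leaving ranks 1..n_t for the
    nonzero entries and garbage (unused) at the zero positions.
    """
    shifted = np.where(nonzero, absd, -np.inf)
    ranks = sstats.rankdata(shifted, axis=0, method="average")
    n_zero = (~nonzero).sum(axis=0)
    return np.where(nonzero, ranks - n_zero, 0.0)


def _z_to_p(z: np.ndarray) -> np.ndarray:
    return 2.0 * sstats.norm.sf(np.abs(z))


def signrank_p(diffs: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon signed-rank p per column of a trials x T matrix.

    Zero differences are dropped (Wilcoxon's original treatment); columns
    with fewer than 2 nonzero differences get p = 1.
    """
    d = np.atleast_2d(np.asarray(diffs, dtype=float))
    nonzero = d != 0
    r = _masked_ranks(np.abs(d), nonzero)
    w_plus = np.where(d > 0, r, 0.0).sum(axis=0)
    mu = r.sum(axis=0) / 2.0
    var = (r**2).sum(axis=0) / 4.0
    n_t = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (w_plus - mu) / np.sqrt(var), 0.0)
    p = _z_to_p(z)
    p[n_t < 2] = 1.0
    return p


def signrank_flip_p(diffs: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """Signed-rank p-values for sign-flipped versions of ``diffs``.

    ``flips`` is a (P, n_trials) matrix of +/-1; returns a (P, T) p matrix
    consistent with :func:`signrank_p` (``flips`` of all ones reproduces it).
    """
    d = np.atleast_2d(np.asarray(diffs, dtype=float))
    flips = np.asarray(flips, dtype=float)
    nonzero = d != 0
    r = _masked_ranks(np.abs(d), nonzero)
    signed_r = r * np.sign(d)
    r_sum = r.sum(axis=0)
    w_plus = 0.5 * (r_sum[None, :] + flips @ signed_r)
    mu = r_sum / 2.0
    var = (r**2).sum(axis=0) / 4.0
    n_t = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (w_plus - mu[None, :]) / np.sqrt(var)[None, :], 0.0)
    p = _z_to_p(z)
    p[:, n_t < 2] = 1.0
    return p


def _pooled_rank_moments(r: np.ndarray, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    n = r.shape[0]
    n_b = n - n_a
    mu = n_a * (n + 1) / 2.0
    rbar = r.mean(axis=0)
    s2 = ((r - rbar) ** 2).sum(axis=0) / (n - 1)
    var = n_a * n_b * s2 / n
    return mu, var


def ranksum_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum (Mann-Whitney) p per column for two matrices."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    pooled = np.vstack([a, b])
    r = sstats.rankdata(pooled, axis=0, method="average")
    w_a = r[: a.shape[0]].sum(axis=0)
    mu, var = _pooled_rank_moments(r, a.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (w_a - mu) / np.sqrt(var), 0.0)
    return _z_to_p(z)


def ranksum_assign_p(pooled: np.ndarray, assign: np.ndarray) -> np.ndarray:
    """Rank-sum p-values for arbitrary group-A assignments of pooled trials.

    ``pooled`` is (n, T); ``assign`` is a (P, n) boolean matrix whose rows
    select group A (all rows must select the same group size). Returns a
    (P, T) p matrix consistent with :func:`ranksum_p`.
    """
    pooled = np.atleast_2d(np.asarray(pooled, dtype=float))
    assign = np.asarray(assign)
    n_a = int(assign[0].sum())
    if not np.all(assign.sum(axis=1) == n_a):
        raise ValueError("all assignment rows must select the same group size")
    r = sstats.rankdata(pooled, axis=0, method="average")
    w_a = assign.astype(float) @ r
    mu, var = _pooled_rank_moments(r, n_a)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (w_a - mu) / np.sqrt(var)[None, :], 0.0)
    return _z_to_p(z)


# ---------------------------------------------------------------------------
# runs / clusters


def find_runs(sig: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a 1-D boolean array as half-open (start, end)."""
    sig = np.asarray(sig, dtype=bool)
    if sig.ndim != 1:
        raise ValueError("find_runs expects a 1-D array")
    padded = np.concatenate([[False], sig, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def longest_run(sig: np.ndarray) -> tuple[int, int] | None:
    """Longest run of True; earliest wins ties; None if no True."""
    runs = find_runs(sig)
    if not runs:
        return None
    lengths = [e - s for s, e in runs]
    return runs[int(np.argmax(lengths))]  # argmax returns first maximum


def has_run(sig: np.ndarray, min_samples: int) -> np.ndarray:
    """Row-wise: does a run of >= min_samples True exist? (P, T) -> (P,)."""
    sig = np.atleast_2d(np.asarray(sig, dtype=bool))
    if min_samples <= 1:
        return sig.any(axis=1)
    if sig.shape[1] < min_samples:
        return np.zeros(sig.shape[0], dtype=bool)
    c = np.cumsum(sig, axis=1)
    c = np.concatenate([np.zeros((sig.shape[0], 1), dtype=int), c], axis=1)
    window_sums = c[:, min_samples:] - c[:, :-min_samples]
    return (window_sums == min_samples).any(axis=1)


# ---------------------------------------------------------------------------
# permutation helpers


def all_sign_flips(n: int) -> np.ndarray:
    """All 2^n sign vectors, shape (2^n, n), entries +/-1."""
    if n > 20:
        raise ValueError("sign-flip space too large to enumerate")
    return np.array(list(product((1.0, -1.0), repeat=n)))


def all_assignments(n: int, n_a: int) -> np.ndarray:
    """All C(n, n_a) boolean group-A assignment rows."""
    rows = []
    for idx in combinations(range(n), n_a):
        row = np.zeros(n, dtype=bool)
        row[list(idx)] = True
        rows.append(row)
    return np.array(rows)


def perm_pvalue(observed: float, null: np.ndarray, mode: str = "ge") -> float:
    """Monte-Carlo permutation p with add-one correction.

    ``mode="ge"`` counts null >= observed (count statistics); ``"abs"``
    counts |null| >= |observed| (two-sided difference statistics).
    """
    null = np.asarray(null, dtype=float)
    if mode == "ge":
        extreme = np.sum(null >= observed - 1e-12)
    elif mode == "abs":
        extreme = np.sum(np.abs(null) >= abs(observed) - 1e-12)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float((1 + extreme) / (1 + len(null)))
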