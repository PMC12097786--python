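"""Effect-latency time course and two-component Gaussian curve fit.

Across selective neurons, the number showing a significant effect at each
millisecond post-stimulus forms a counts trace. Whether effect timings are
bimodal (an early, ~150-ms cluster and a late, ~300-ms cluster) is assessed
by fitting an amplitude-weighted sum of two Gaussian curves to that trace by
least squares — curve fitting to the counts, not a probability-density EM
fit — and comparing its MSE to the best single-Gaussian fit. Bimodality is
declared when the single-component MSE is more than 4x the two-component
MSE. The optimizer is box-constrained L-BFGS-B; the best of 20
uniformly-random restarts is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import ValidationError
from .selectivity import ClusterResult

__all__ = ["SignificanceTrace", "MixtureFit", "significance_trace", "fit_two_gaussian_mixture"]

MEAN_BOUNDS = (0.0, 400.0)
SD_BOUNDS = (10.0, 200.0)
MSE_RATIO_THRESHOLD = 4.0


@dataclass
class SignificanceTrace:
    """Neurons with a significant effect per 1-ms time point."""

    time_ms: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != self.time_ms.shape:
            raise ValidationError("counts and time axis must align")


@dataclass
class MixtureFit:
    """Best-of-restarts parameters, early component first."""

    weights: tuple[float, float]
    means_ms: tuple[float, float]
    sds_ms: tuple[float, float]
    mse: float
    mse_1c: float
    n_restarts: int

    @property
    def mse_ratio_1c(self) -> float:
        return self.mse_1c / self.mse if self.mse > 0 else np.inf

    @property
    def bimodal(self) -> bool:
        return self.mse_ratio_1c > MSE_RATIO_THRESHOLD


def significance_trace(
    clusters: list[ClusterResult],
    window_ms: tuple[int, int] = (0, 400),
) -> SignificanceTrace:
    """Count, per millisecond, the neurons whose cluster covers that time."""
    t = np.arange(window_ms[0], window_ms[1])
    counts = np.zeros_like(t)
    for c in clusters:
        if c is None:
            continue
        counts += (t >= c.start_ms) & (t < c.end_ms)
    return SignificanceTrace(time_ms=t, counts=counts)


def _gauss_sum(t: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sum of amplitude-weighted Gaussian curves; params = (w, m, s) * k."""
    out = np.zeros_like(t, dtype=float)
    for w, m, s in params.reshape(-1, 3):
        out += w * np.exp(-0.5 * ((t - m) / s) ** 2)
    return out


def _fit_k(
    t: np.ndarray,
    y: np.ndarray,
    k: int,
    n_restarts: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    w_hi = max(2.0 * y.max(), 1.0)
    bounds = [(0.0, w_hi), MEAN_BOUNDS, SD_BOUNDS] * k

    def mse(params: np.ndarray) -> float:
        r = _gauss_sum(t, params) - y
        return float(np.mean(r**2))

    best_params, best_mse = None, np.inf
    for _ in range(n_restarts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(mse, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_mse:
            best_params, best_mse = res.x, float(res.fun)
    return best_params, best_mse


def fit_two_gaussian_mixture(
    trace: SignificanceTrace,
    n_restarts: int = 20,
    seed: int | np.random.Generator | None = None,
) -> MixtureFit:
    """Least-squares fit of two Gaussian curves to a counts trace.

    Each restart draws (weight, mean, sd) for both components uniformly
    inside the constraint boxes (means in [0, 400] ms, sds in [10, 200] ms,
    weights >= 0); the best of ``n_restarts`` local optimizations is kept.
    The best single-Gaussian fit uses the same protocol, and their MSE ratio
    is the bimodality criterion. Components are reported early-mean first.
    """
    y = trace.counts.astype(float)
    if not np.any(y > 0):
        raise ValidationError("significance trace is identically zero")
    t = trace.time_ms.astype(float)
    rng = np.random.default_rng(seed)

    params2, mse2 = _fit_k(t, y, 2, n_restarts, rng)
    _, mse1 = _fit_k(t, y, 1, n_restarts, rng)

    (w1, m1, s1), (w2, m2, s2) = params2.reshape(2, 3)
    if m2 < m1:
        (w1, m1, s1), (w2, m2, s2) = (w2, m2, s2), (w1, m1, s1)
    return MixtureFit(
        weights=(float(w1), float(w2)),
        means_ms=(float(m1), float(m2)),
        sds_ms=(float(s1), float(s2)),
        mse=mse2,
        mse_1c=mse1,
        n_restarts=n_restarts,
    )
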