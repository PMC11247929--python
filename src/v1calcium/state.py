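"""Spontaneous-activity analysis against behavioral state.

Frames are segmented into stationary (speed <= 1 cm/s) and running
(speed > 1 cm/s).  Activity-locomotion coupling is measured as the
zero-lag Pearson correlation between the 5 Hz activity and speed traces,
with significance from a permutation null (1000 random permutations of
the speed series, p < 0.05); significant neurons additionally report the
peak of the cross-correlogram and its lag.  Pairwise synchrony applies
the same zero-lag + permutation machinery to every unordered neuron pair.

Lag sign convention: positive lag means neural activity lags (follows)
locomotion — ``r(L) = corr(activity[t], speed[t - L])``.

The default null permutes individual samples, which destroys
autocorrelation; for strongly autocorrelated signals a circular-shift
null is available via ``null="circular"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (DegenerateTraceError, InsufficientDataError,
                     InvalidArgumentError, StateMissingError)
from .preprocess import ActivityMatrix

__all__ = [
    "StateLabels",
    "CorrelationResult",
    "classify_frames",
    "state_means",
    "xcorr_speed",
    "pairwise_synchrony",
    "synchrony_summary",
]


@dataclass
class StateLabels:
    """Per-frame behavioral state; True = running (speed > threshold)."""

    running: np.ndarray
    threshold: float = 1.0

    @property
    def n_run(self) -> int:
        return int(self.running.sum())

    @property
    def n_stationary(self) -> int:
        return int((~self.running).sum())


@dataclass
class CorrelationResult:
    """Zero-lag correlation with permutation-null significance."""

    r_zero: float
    lags_s: np.ndarray
    correlogram: np.ndarray
    p: float
    significant: bool
    peak_r: float | None = None
    peak_lag_s: float | None = None


def classify_frames(speed, threshold: float = 1.0) -> StateLabels:
    """Label frames running (speed > threshold) vs stationary (<=)."""
    speed = np.asarray(speed, dtype=float)
    if not np.all(np.isfinite(speed)):
        raise InvalidArgumentError("speed contains non-finite values")
    return StateLabels(running=speed > threshold, threshold=threshold)


def state_means(activity: ActivityMatrix, labels: StateLabels) -> pd.DataFrame:
    """Per-neuron mean activity by state and the run - stationary difference."""
    if activity.n_frames != labels.running.size:
        raise InvalidArgumentError("activity and labels differ in frame count")
    if labels.n_run == 0:
        raise StateMissingError("no running frames; session should be excluded")
    if labels.n_stationary == 0:
        raise StateMissingError("no stationary frames")
    run = labels.running
    m_run = activity.values[:, run].mean(axis=1)
    m_stat = activity.values[:, ~run].mean(axis=1)
    return pd.DataFrame({
        "roi_id": activity.roi_ids,
        "mean_stationary": m_stat,
        "mean_run": m_run,
        "run_minus_stationary": m_run - m_stat,
    })


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        raise DegenerateTraceError("zero-variance input to correlation")
    return float((x @ y) / denom)


def _correlogram(activity: np.ndarray, speed: np.ndarray, max_lag: int):
    lags = np.arange(-max_lag, max_lag + 1)
    rs = np.empty(lags.size)
    for k, lag in enumerate(lags):
        if lag > 0:  # activity follows speed
            rs[k] = _pearson(activity[lag:], speed[:-lag])
        elif lag < 0:
            rs[k] = _pearson(activity[:lag], speed[-lag:])
        else:
            rs[k] = _pearson(activity, speed)
    return lags, rs


def _perm_null_r(x: np.ndarray, y: np.ndarray, n_shuffles: int,
                 rng: np.random.Generator, null: str) -> np.ndarray:
    """|r| of x against n_shuffles permutations (or circular shifts) of y."""
    n = y.size
    xc = x - x.mean()
    xc /= np.sqrt(xc @ xc)
    if null == "circular":
        shifts = rng.integers(1, n, size=n_shuffles)
        perms = np.stack([np.roll(y, s) for s in shifts])
    elif null == "permutation":
        perms = rng.permuted(np.tile(y, (n_shuffles, 1)), axis=1)
    else:
        raise InvalidArgumentError(f"unknown null {null!r}")
    perms = perms - perms.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", perms, perms))
    return (perms @ xc) / norms


def xcorr_speed(activity_5hz, speed_5hz, rate: float = 5.0,
                max_lag_s: float = 10.0, n_shuffles: int = 1000,
                alpha: float = 0.05, seed: int = 0,
                null: str = "permutation") -> CorrelationResult:
    """Zero-lag activity-speed correlation with a shuffle test.

    p = (1 + #{|r_shuffled| >= |r_zero|}) / (1 + n_shuffles); the peak of
    the cross-correlogram (largest |r|) and its lag are reported only when
    p < alpha.
    """
    x = np.asarray(activity_5hz, dtype=float)
    y = np.asarray(speed_5hz, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("activity and speed must be equal-length 1-D")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateTraceError("zero-variance trace")
    rng = np.random.default_rng(seed)
    r_zero = _pearson(x, y)
    null_r = _perm_null_r(x, y, n_shuffles, rng, null)
    p = (1 + np.sum(np.abs(null_r) >= abs(r_zero))) / (1 + n_shuffles)
    max_lag = int(round(max_lag_s * rate))
    lags, rs = _correlogram(x, y, max_lag)
    significant = p < alpha
    peak_r = peak_lag = None
    if significant:
        k = int(np.argmax(np.abs(rs)))
        peak_r = float(rs[k])
        peak_lag = float(lags[k] / rate)
    return CorrelationResult(r_zero=r_zero, lags_s=lags / rate, correlogram=rs,
                             p=float(p), significant=bool(significant),
                             peak_r=peak_r, peak_lag_s=peak_lag)


def pairwise_synchrony(activity_5hz: np.ndarray, n_shuffles: int = 1000,
                       alpha: float = 0.05, seed: int = 0,
                       null: str = "permutation") -> pd.DataFrame:
    """Zero-lag correlation + shuffle test for every unordered neuron pair.

    ``activity_5hz`` is (neurons x samples) at 5 Hz, inclusion filter
    already applied.  Returns one row per pair (i < j) with r, p and a
    significance flag.
    """
    act = np.asarray(activity_5hz, dtype=float)
    if act.ndim != 2 or act.shape[0] < 2:
        raise InsufficientDataError("need >= 2 neurons for pairwise synchrony")
    if np.any(np.std(act, axis=1) == 0):
        raise DegenerateTraceError("a neuron has zero variance")
    rng = np.random.default_rng(seed)
    n = act.shape[0]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            r = _pearson(act[i], act[j])
            null_r = _perm_null_r(act[i], act[j], n_shuffles, rng, null)
            p = (1 + np.sum(np.abs(null_r) >= abs(r))) / (1 + n_shuffles)
            rows.append((i, j, r, p, p < alpha))
    return pd.DataFrame(rows, columns=["i", "j", "r_zero", "p", "significant"])


def synchrony_summary(pairs: pd.DataFrame) -> dict:
    """Fraction of significant pairs and moments of the r distribution."""
    return {
        "n_pairs": int(len(pairs)),
        "frac_significant": float(pairs["significant"].mean()),
        "mean_r": float(pairs["r_zero"].mean()),
        "median_r": float(pairs["r_zero"].median()),
    }


def density_plot(mean_stat, mean_run, ax=None, gridsize: int = 100):
    """Optional 2-D Gaussian-KDE visualization of per-state mean activity."""
    from scipy.stats import gaussian_kde
    import matplotlib.pyplot as plt

    xy = np.vstack([np.asarray(mean_stat), np.asarray(mean_run)])
    kde = gaussian_kde(xy)
    lo, hi = xy.min() - 0.5, xy.max() + 0.5
    grid = np.linspace(lo, hi, gridsize)
    xx, yy = np.meshgrid(grid, grid)
    zz = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    if ax is None:
        _, ax = plt.subplots()
    ax.contourf(xx, yy, zz, levels=20)
    ax.plot([lo, hi], [lo, hi], "w--", lw=0.8)
    ax.set_xlabel("mean standardized dF/F0 (stationary)")
    ax.set_ylabel("mean standardized dF/F0 (running)")
    return ax
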