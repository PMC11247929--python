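"""Locomotion and pupillometry conditioning.

Locomotion: the raw encoder signal is smoothed with a 1-D convolution,
mean-binned to 30 Hz and converted to cm/s with a calibration factor.
Pupillometry: the z-scored blink trace is smoothed with a Hanning window,
differentiated, and velocity threshold crossings define blink onsets and
offsets; intervals are widened by a buffer and merged when close, then the
blink gaps in the pupil trace are re-filled with a cubic spline through the
non-blink samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InvalidArgumentError, NotInterpolatableError

__all__ = [
    "BehaviorTraces",
    "condition_speed",
    "detect_blinks",
    "interpolate_pupil",
    "PupilInterpolation",
    "zscore",
]


@dataclass
class BehaviorTraces:
    """Conditioned behavior series for one session.

    speed is cm/s at ``speed_rate`` (30 Hz by default); pupil_z is the
    z-scored, blink-interpolated pupil area at its native camera rate.
    """

    speed: np.ndarray
    speed_rate: float = 30.0
    pupil_z: np.ndarray | None = None
    pupil_rate: float = 19.06
    blink_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.speed = np.asarray(self.speed, dtype=float)
        if np.any(self.speed < 0):
            raise InvalidArgumentError("speed must be nonnegative")
        for (a0, b0), (a1, _) in zip(self.blink_intervals, self.blink_intervals[1:]):
            if a1 < b0:
                raise InvalidArgumentError("blink intervals overlap or are unsorted")


def zscore(x):
    """(x - mean) / sample SD; the pupillometry normalization."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise InvalidArgumentError("cannot z-score a constant trace")
    return (x - np.mean(x)) / sd


def condition_speed(raw, src_rate: float, target_rate: float = 30.0,
                    kernel=None, calibration: float = 1.0):
    """Smooth, bin and calibrate a raw wheel-speed signal.

    Parameters
    ----------
    raw : array
        Analog samples at ``src_rate``.
    kernel : array, optional
        Smoothing kernel; normalized to unit sum before convolution
        (``same`` mode with edge renormalization).  ``None`` skips smoothing.
    calibration : float
        Multiplicative cm/s-per-unit conversion.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise InvalidArgumentError("empty raw speed signal")
    if target_rate <= 0 or src_rate <= 0:
        raise InvalidArgumentError("rates must be positive")
    if kernel is not None:
        kernel = np.asarray(kernel, dtype=float)
        kernel = kernel / kernel.sum()
        counts = np.convolve(np.ones_like(raw), kernel, mode="same")
        raw = np.convolve(raw, kernel, mode="same") / counts
    step = src_rate / target_rate
    if step < 1:
        raise InvalidArgumentError("target_rate above src_rate; cannot bin up")
    n_bins = int(np.floor(raw.size / step))
    edges = np.floor(np.arange(n_bins + 1) * step).astype(int)
    binned = np.array([raw[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    return calibration * binned


def _hanning_smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width < 3:
        return x.copy()
    win = np.hanning(width)
    win /= win.sum()
    counts = np.convolve(np.ones_like(x), win, mode="same")
    return np.convolve(x, win, mode="same") / counts


def detect_blinks(blink_z, rate: float, smooth_window_s: float = 0.26,
                  vel_threshold: float = 5.0, buffer_s: float = 0.1,
                  merge_gap_s: float = 0.3) -> list[tuple[float, float]]:
    """Detect blink intervals from a z-scored eyelid/blink trace.

    The trace is smoothed with a Hanning window, differentiated, and a
    blink onset is declared where the velocity drops below
    ``-vel_threshold`` (z/s); the matching offset is the next crossing
    above ``+vel_threshold``.  Each interval is widened by ``buffer_s`` on
    both sides and intervals separated by less than ``merge_gap_s`` are
    merged.  Returns sorted, disjoint ``(onset_s, offset_s)`` pairs.
    """
    blink_z = np.asarray(blink_z, dtype=float)
    if rate <= 0 or vel_threshold <= 0 or buffer_s < 0 or merge_gap_s < 0:
        raise InvalidArgumentError("rates and thresholds must be positive")
    width = max(3, int(round(smooth_window_s * rate)))
    smooth = _hanning_smooth(blink_z, width)
    vel = np.gradient(smooth) * rate  # z per second
    duration = (blink_z.size - 1) / rate

    intervals: list[tuple[float, float]] = []
    i = 0
    n = vel.size
    while i < n:
        if vel[i] < -vel_threshold:
            onset = i
            j = i + 1
            while j < n and vel[j] <= vel_threshold:
                j += 1
            if j >= n:
                warnings.warn("unpaired blink onset at trace end; closing at end")
                offset = n - 1
                i = n
            else:
                # offset: end of the reopening (positive-velocity) excursion
                while j < n and vel[j] > vel_threshold:
                    j += 1
                offset = min(j, n - 1)
                i = j
            intervals.append((onset / rate, offset / rate))
        else:
            i += 1

    widened = [
        (max(0.0, a - buffer_s), min(duration, b + buffer_s)) for a, b in intervals
    ]
    merged: list[tuple[float, float]] = []
    for a, b in sorted(widened):
        if merged and a - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


@dataclass
class PupilInterpolation:
    """Gap-filled pupil trace plus bookkeeping about edge extrapolation."""

    values: np.ndarray
    extrapolated_intervals: list[tuple[float, float]]


def interpolate_pupil(pupil_z, blinks, rate: float) -> PupilInterpolation:
    """Replace blink samples with a cubic spline through non-blink samples.

    Samples outside blink intervals are returned bit-identical; intervals
    touching the trace edges are filled by spline extrapolation and listed
    in ``extrapolated_intervals``.
    """
    pupil_z = np.asarray(pupil_z, dtype=float)
    n = pupil_z.size
    if n == 0:
        raise InvalidArgumentError("empty pupil trace")
    t = np.arange(n) / rate
    mask = np.zeros(n, dtype=bool)
    for a, b in blinks:
        if a > t[-1] or b < 0:
            raise InvalidArgumentError(f"blink interval ({a}, {b}) outside trace span")
        mask |= (t >= a) & (t <= b)
    if not blinks:
        return PupilInterpolation(pupil_z.copy(), [])
    if mask.all():
        raise NotInterpolatableError("blink intervals cover the entire trace")
    spline = CubicSpline(t[~mask], pupil_z[~mask])
    out = pupil_z.copy()
    out[mask] = spline(t[mask])
    first_good, last_good = t[~mask][0], t[~mask][-1]
    extrapolated = [(a, b) for a, b in blinks if a < first_good or b > last_good]
    return PupilInterpolation(out, extrapolated)
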