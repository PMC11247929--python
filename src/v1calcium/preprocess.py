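"""Raw fluorescence to standardized dF/F0.

The preprocessing chain applied to every somatic ROI trace is

    F  = F_somatic - r * F_neuropil          (neuropil correction)
    F0 = rolling 30th percentile of F        (150 s centered window)
    dF/F0 = (F - F0) / F0
    standardized dF/F0 = (dF/F0 - median) / SD

followed by an inclusion rule (max standardized dF/F0 >= 3) and, for
correlation analyses, resampling to 5 Hz (linear interpolation to 10 Hz,
5-point moving average, decimation by 2).

Conventions used throughout the package: sample standard deviation
(ddof=1); percentiles by linear interpolation between order statistics;
centered windows truncated at trace edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateBaselineError, DegenerateTraceError, InvalidArgumentError

__all__ = [
    "ActivityMatrix",
    "NEUROPIL_FACTORS",
    "neuropil_factor",
    "neuropil_correct",
    "rolling_percentile_baseline",
    "dff",
    "standardize",
    "roi_inclusion_mask",
    "resample_5hz",
    "preprocess_traces",
]

#: Default neuropil scaling factor per calcium indicator.
NEUROPIL_FACTORS = {
    "GCaMP6f": 0.7,
    "GCaMP7s": 0.7,
    "jGCaMP8m": 0.8,
}


def neuropil_factor(indicator: str) -> float:
    """Return the default neuropil factor r for a calcium indicator label."""
    try:
        return NEUROPIL_FACTORS[indicator]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown indicator {indicator!r}; known: {sorted(NEUROPIL_FACTORS)}"
        ) from None


@dataclass
class ActivityMatrix:
    """Standardized dF/F0 for one session.

    Attributes
    ----------
    values : (n_neurons, n_frames) float array
        Standardized dF/F0 (median 0, sample SD 1 per neuron).
    frame_rate : float
        Acquisition rate in Hz.
    roi_ids : array of int
        ROI labels, one per row.
    included : bool array
        Per-ROI inclusion flag (max standardized dF/F0 >= threshold).
    """

    values: np.ndarray
    frame_rate: float
    roi_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    included: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("values must be 2-D (neurons x frames)")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("activity contains non-finite entries")
        if self.frame_rate <= 0:
            raise InvalidArgumentError("frame_rate must be positive")
        n = self.values.shape[0]
        if self.roi_ids is None:
            self.roi_ids = np.arange(n)
        else:
            self.roi_ids = np.asarray(self.roi_ids)
        if self.included is None:
            self.included = np.ones(n, dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)
        if len(self.roi_ids) != n or len(self.included) != n:
            raise InvalidArgumentError("roi_ids/included length mismatch")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def neuropil_correct(f_soma, f_neuropil, r: float):
    """Subtract the scaled neuropil trace: ``F = f_soma - r * f_neuropil``.

    Accepts 1-D traces or 2-D (neurons x frames) arrays of matching shape.
    """
    f_soma = np.asarray(f_soma, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_soma.shape != f_neuropil.shape:
        raise InvalidArgumentError(
            f"shape mismatch: soma {f_soma.shape} vs neuropil {f_neuropil.shape}"
        )
    if not 0 <= r < 1:
        raise InvalidArgumentError(f"neuropil factor r={r} outside [0, 1)")
    return f_soma - r * f_neuropil


def rolling_percentile_baseline(F, frame_rate: float, window_s: float = 150.0,
                                percentile: float = 30.0):
    """Rolling-percentile baseline F0.

    ``F0[t]`` is the ``percentile``-th percentile of F over a centered
    window of ``window_s`` seconds around frame t, truncated at the trace
    edges.  Percentile uses linear interpolation between order statistics.
    Works on 1-D traces or 2-D (neurons x frames) arrays.
    """
    F = np.asarray(F, dtype=float)
    if F.size == 0:
        raise InvalidArgumentError("empty trace")
    if frame_rate <= 0:
        raise InvalidArgumentError("frame_rate must be positive")
    n_win = int(round(window_s * frame_rate))
    if n_win < 2:
        raise InvalidArgumentError(
            f"window of {window_s}s at {frame_rate}Hz is {n_win} < 2 frames"
        )
    one_d = F.ndim == 1
    mat = np.atleast_2d(F)
    n_win = min(n_win, mat.shape[1])
    # pandas implements the exact centered/truncated rolling quantile with
    # linear interpolation; window spans [t - n_win//2, t + (n_win+1)//2 - 1]
    # (an even-length window takes its extra sample on the left).
    df = pd.DataFrame(mat.T)
    out = (
        df.rolling(n_win, center=True, min_periods=1)
        .quantile(percentile / 100.0, interpolation="linear")
        .to_numpy()
        .T
    )
    return out[0] if one_d else out


def dff(F, F0):
    """Relative fluorescence change ``(F - F0) / F0``.

    Raises
    ------
    DegenerateBaselineError
        If any F0 entry is <= 0 (names the offending frames).
    """
    F = np.asarray(F, dtype=float)
    F0 = np.asarray(F0, dtype=float)
    if F.shape != F0.shape:
        raise InvalidArgumentError("F and F0 shapes differ")
    bad = np.argwhere(F0 <= 0)
    if bad.size:
        frames = np.unique(bad[:, -1])
        raise DegenerateBaselineError(frames)
    return (F - F0) / F0


def standardize(trace, axis: int = -1):
    """Center by the median and scale by the sample SD (ddof=1)."""
    trace = np.asarray(trace, dtype=float)
    med = np.median(trace, axis=axis, keepdims=True)
    sd = np.std(trace, axis=axis, ddof=1, keepdims=True)
    if np.any(sd <= 0):
        raise DegenerateTraceError("zero-variance trace cannot be standardized")
    return (trace - med) / sd


def roi_inclusion_mask(std_values, threshold: float = 3.0):
    """Per-ROI flag: True iff max standardized dF/F0 >= threshold."""
    std_values = np.atleast_2d(np.asarray(std_values, dtype=float))
    return np.max(std_values, axis=1) >= threshold


def _moving_average_truncated(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; windows truncated at the edges."""
    kernel = np.ones(width)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def resample_5hz(trace, src_rate: float):
    """Resample a trace to 5 Hz for correlation analyses.

    Linear interpolation onto a 10 Hz grid, centered 5-point moving
    average (edge windows truncated), then every 2nd sample kept.
    """
    trace = np.asarray(trace, dtype=float)
    if src_rate <= 0:
        raise InvalidArgumentError("src_rate must be positive")
    one_d = trace.ndim == 1
    mat = np.atleast_2d(trace)
    n = mat.shape[1]
    duration = (n - 1) / src_rate
    t10 = np.arange(int(np.floor(duration * 10)) + 1) / 10.0
    if len(t10) < 5:
        raise InvalidArgumentError("trace shorter than the 5-point smoothing window")
    t_src = np.arange(n) / src_rate
    out = np.empty((mat.shape[0], len(t10)))
    for i in range(mat.shape[0]):
        interp = np.interp(t10, t_src, mat[i])
        out[i] = _moving_average_truncated(interp, 5)
    out = out[:, ::2]
    return out[0] if one_d else out


def preprocess_traces(f_soma, f_neuropil, frame_rate: float, r: float = 0.7,
                      window_s: float = 150.0, percentile: float = 30.0,
                      inclusion_threshold: float = 3.0,
                      roi_ids=None) -> ActivityMatrix:
    """Full chain: neuropil correction -> F0 -> dF/F0 -> standardize -> mask."""
    F = neuropil_correct(f_soma, f_neuropil, r)
    F0 = rolling_percentile_baseline(F, frame_rate, window_s, percentile)
    d = dff(F, F0)
    std = standardize(d)
    std2 = np.atleast_2d(std)
    return ActivityMatrix(
        values=std2,
        frame_rate=frame_rate,
        roi_ids=roi_ids,
        included=roi_inclusion_mask(std2, inclusion_threshold),
    )
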