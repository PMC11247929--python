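"""Orientation-tuning statistics.

The per-trial visual response is the mean standardized dF/F0 over the
grating window minus the mean over the 0.5 s pre-stimulus baseline.  A
neuron is *responsive* if at least two trials exceed 3x the SD of their
own baseline window.  Tuning statistics on the min-max-normalized mean
response curve R(theta):

    gOSI = | sum R(theta) e^{2i theta} | / sum R(theta)
    DSI  = (R_pref - R_null) / (R_pref + R_null),  R_null at pref + 180 deg
    SNR  = mean over theta of mean(reps)^2 / SD(reps)

Signal correlation is the Pearson correlation of two neurons' mean tuning
curves computed on disjoint repetition halves (to exclude shared trial
noise); noise correlation is the mean over orientations of the
trial-by-trial correlation at fixed orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (DegenerateTuningError, InsufficientDataError,
                     InvalidArgumentError, InvalidScheduleError)
from .preprocess import ActivityMatrix
from .synthetic import StimulusSchedule

__all__ = [
    "TrialResponseTable",
    "TuningResult",
    "extract_trial_responses",
    "responsive_mask",
    "minmax_normalize",
    "gosi",
    "dsi",
    "snr",
    "signal_correlation",
    "noise_correlation",
    "orientation_analysis",
]


@dataclass
class TrialResponseTable:
    """Per-neuron, per-trial baseline-subtracted responses.

    ``responses`` and ``baseline_sd`` are (neurons x trials); ``trials``
    carries the schedule metadata (orientation_deg, contrast_pct, blank)
    plus any later-added labels such as the locomotion state.
    """

    responses: np.ndarray
    baseline_sd: np.ndarray
    trials: pd.DataFrame
    roi_ids: np.ndarray

    def __post_init__(self):
        if self.responses.shape != self.baseline_sd.shape:
            raise InvalidArgumentError("responses/baseline_sd shape mismatch")
        if self.responses.shape[1] != len(self.trials):
            raise InvalidArgumentError("trial count mismatch")
        if not np.all(np.isfinite(self.responses)):
            raise InvalidArgumentError("non-finite responses")

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    def repetition_matrix(self, neuron: int):
        """(orientations, repetitions) response matrix for one neuron.

        Uses non-blank trials; requires equal repeat counts per
        orientation (the study design).  Rows follow sorted orientation.
        """
        ok = ~self.trials["blank"].to_numpy()
        oris = self.trials.loc[ok, "orientation_deg"].to_numpy()
        resp = self.responses[neuron, ok]
        uniq = np.unique(oris)
        counts = {o: int((oris == o).sum()) for o in uniq}
        n_rep = min(counts.values())
        if len(set(counts.values())) != 1:
            warnings.warn("unequal repeats per orientation; truncating")
        mat = np.stack([resp[oris == o][:n_rep] for o in uniq])
        return uniq, mat


@dataclass
class TuningResult:
    """Per-neuron orientation-tuning summary."""

    orientations_deg: np.ndarray
    mean_response: np.ndarray          # raw R-bar(theta)
    preferred_orientation: float
    aligned_curve: np.ndarray          # preferred bin shifted to 90 deg
    gosi: float
    dsi: float
    snr: float
    responsive: bool


def extract_trial_responses(activity: ActivityMatrix,
                            schedule: StimulusSchedule,
                            baseline_s: float = 0.5) -> TrialResponseTable:
    """Baseline-subtracted mean response per neuron and trial.

    Windows are half-open in frames: stimulus [floor(on*rate),
    floor(off*rate)), baseline [floor((on - baseline_s)*rate),
    floor(on*rate)).  ``baseline_sd`` is the sample SD of the baseline
    window (ddof=1).
    """
    rate = activity.frame_rate
    n_frames = activity.n_frames
    vals = activity.values
    n_trials = schedule.n_trials
    responses = np.empty((activity.n_neurons, n_trials))
    base_sd = np.empty_like(responses)
    for t, row in enumerate(schedule.trials.itertuples(index=False)):
        a = int(np.floor(row.stim_on_s * rate))
        b = int(np.floor(row.stim_off_s * rate))
        a0 = int(np.floor((row.stim_on_s - baseline_s) * rate))
        if a0 < 0 or b > n_frames or a >= b:
            raise InvalidScheduleError(
                f"trial {t} window [{a0}, {b}) outside recording of "
                f"{n_frames} frames"
            )
        responses[:, t] = vals[:, a:b].mean(axis=1) - vals[:, a0:a].mean(axis=1)
        base_sd[:, t] = np.std(vals[:, a0:a], axis=1, ddof=1)
    return TrialResponseTable(responses=responses, baseline_sd=base_sd,
                              trials=schedule.trials.copy(),
                              roi_ids=activity.roi_ids)


def responsive_mask(table: TrialResponseTable, k: float = 3.0,
                    min_trials: int = 2) -> np.ndarray:
    """True iff >= ``min_trials`` trials have response > k x baseline SD.

    Blank trials are not counted.  Trials with zero baseline SD use a
    threshold of 0, so any positive response counts.
    """
    if table.responses.size == 0:
        raise InvalidArgumentError("empty response table")
    ok = ~table.trials["blank"].to_numpy()
    hits = table.responses[:, ok] > k * table.baseline_sd[:, ok]
    return hits.sum(axis=1) >= min_trials


def minmax_normalize(R):
    """Map responses to [0, 1] via (R - Rmin) / (Rmax - Rmin)."""
    R = np.asarray(R, dtype=float)
    lo, hi = R.min(), R.max()
    if hi <= lo:
        raise DegenerateTuningError("flat response vector; gOSI/DSI undefined")
    return (R - lo) / (hi - lo)


def gosi(R, theta_deg) -> float:
    """Global orientation selectivity index on the doubled angle.

    ``|sum R e^{2i theta}| / sum R`` with theta in radians; R should be
    nonnegative (min-max normalized responses).
    """
    R = np.asarray(R, dtype=float)
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    total = R.sum()
    if total <= 0:
        raise DegenerateTuningError("sum of responses is zero")
    return float(np.abs(np.sum(R * np.exp(2j * theta))) / total)


def dsi(R, theta_deg) -> float:
    """Direction selectivity index: (Rpref - Rnull) / (Rpref + Rnull).

    Rpref is the response at the preferred direction (argmax of R, ties
    to the lowest angle); Rnull is the response at pref + 180 deg.
    """
    R = np.asarray(R, dtype=float)
    theta = np.asarray(theta_deg, dtype=float) % 360.0
    k = int(np.argmax(R))
    null_angle = (theta[k] + 180.0) % 360.0
    match = np.isclose(theta, null_angle)
    if not match.any():
        raise InvalidArgumentError(
            f"no orientation at {null_angle} deg opposite the preferred"
        )
    r_pref, r_null = R[k], float(R[match][0])
    if r_pref + r_null == 0:
        raise DegenerateTuningError("Rpref + Rnull = 0")
    return float((r_pref - r_null) / (r_pref + r_null))


def snr(rep_matrix) -> float:
    """Response SNR: mean over orientations of mean(reps)^2 / SD(reps).

    ``rep_matrix`` is (orientations x repetitions).  Orientations with
    zero SD are excluded with a warning; all-undefined raises.
    """
    mat = np.asarray(rep_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise InsufficientDataError("need >= 2 repetitions per orientation")
    means = mat.mean(axis=1)
    sds = mat.std(axis=1, ddof=1)
    ok = sds > 0
    if not ok.any():
        raise DegenerateTuningError("zero SD at every orientation")
    if not ok.all():
        warnings.warn("zero-SD orientation(s) excluded from SNR average")
    return float(np.mean(means[ok] ** 2 / sds[ok]))


def _split_half(n_rep: int, rng: np.random.Generator):
    """Random disjoint halves of repetition indices; odd n gives ceil to j."""
    perm = rng.permutation(n_rep)
    half = (n_rep + 1) // 2
    return perm[:half], perm[half:]


def signal_correlation(trials_j, trials_k, seed: int = 0) -> float:
    """Split-half signal correlation between two neurons.

    ``trials_j``/``trials_k`` are (orientations x repetitions) matrices
    over the same orientation set.  Neuron j's tuning curve is averaged
    over a random half of the repetitions and neuron k's over the other
    half; returns the Pearson correlation of the two curves.
    """
    a = np.asarray(trials_j, dtype=float)
    b = np.asarray(trials_k, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise InvalidArgumentError("orientation sets differ")
    if a.shape[0] < 2:
        raise InsufficientDataError("need >= 2 orientations")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise InsufficientDataError("need >= 2 repetitions")
    rng = np.random.default_rng(seed)
    idx_j, idx_k = _split_half(min(a.shape[1], b.shape[1]), rng)
    curve_j = a[:, idx_j].mean(axis=1)
    curve_k = b[:, idx_k].mean(axis=1)
    return float(np.corrcoef(curve_j, curve_k)[0, 1])


def noise_correlation(trials_j, trials_k) -> float:
    """Mean over orientations of the trialwise Pearson correlation.

    Requires matched repetition order.  Orientations where either
    repetition vector has zero variance are skipped with a warning.
    """
    a = np.asarray(trials_j, dtype=float)
    b = np.asarray(trials_k, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("repetition matrices must match in shape")
    rs = []
    for row_a, row_b in zip(a, b):
        if np.std(row_a) == 0 or np.std(row_b) == 0:
            warnings.warn("zero-variance orientation skipped in noise corr")
            continue
        rs.append(np.corrcoef(row_a, row_b)[0, 1])
    if not rs:
        raise DegenerateTuningError("no orientation with variance")
    return float(np.mean(rs))


def _aligned_curve(mean_resp: np.ndarray, orientations: np.ndarray,
                   pref_idx: int) -> np.ndarray:
    """Circularly shift the tuning curve so the preferred bin sits at 90 deg."""
    step = 360.0 / len(orientations)
    target = int(round(90.0 / step))
    return np.roll(mean_resp, target - pref_idx)


def orientation_analysis(table: TrialResponseTable, k: float = 3.0,
                         min_trials: int = 2) -> list[TuningResult]:
    """Full per-neuron tuning summary for an orientation session.

    Trials are pooled across locomotion states.  Preferred orientation is
    the argmax of the mean response curve (ties to the lowest angle);
    gOSI/DSI are computed on the min-max-normalized curve.  Neurons with a
    flat curve are skipped with a warning (returned entry is None).
    """
    responsive = responsive_mask(table, k=k, min_trials=min_trials)
    out: list[TuningResult] = []
    for n in range(table.n_neurons):
        oris, mat = table.repetition_matrix(n)
        mean_resp = mat.mean(axis=1)
        pref_idx = int(np.argmax(mean_resp))
        try:
            norm = minmax_normalize(mean_resp)
        except DegenerateTuningError:
            warnings.warn(f"neuron {n}: flat tuning curve, skipped")
            out.append(None)
            continue
        out.append(TuningResult(
            orientations_deg=oris,
            mean_response=mean_resp,
            preferred_orientation=float(oris[pref_idx]),
            aligned_curve=_aligned_curve(mean_resp, oris, pref_idx),
            gosi=gosi(norm, oris),
            dsi=dsi(norm, oris),
            snr=snr(mat),
            responsive=bool(responsive[n]),
        ))
    return out
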