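"""Contrast-response analysis.

Per-trial responses (from :mod:`v1calcium.tuning`) are averaged over all
orientations at each contrast, overall and split by the locomotion state
of the trial (running = mean speed during the grating window > 1 cm/s).
Blank (0%-contrast) trials are summarized separately and never enter the
contrast curve or the center of mass.  Contrast preference is summarized
by the log-scale center of mass

    cCOM = exp( sum_c Rc ln c / sum_c Rc )

with negative weights floored at zero, and by a preference class from the
argmax of the contrast curve: low if the preferred contrast is 5 or 10%,
high if 60 or 80%, otherwise "other".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidScheduleError, UndefinedCCOMError
from .synthetic import StimulusSchedule
from .tuning import TrialResponseTable

__all__ = [
    "ContrastResult",
    "label_trial_state",
    "contrast_curve",
    "ccom",
    "preference_class",
    "contrast_analysis",
    "LOW_CONTRASTS",
    "HIGH_CONTRASTS",
]

LOW_CONTRASTS = (5.0, 10.0)
HIGH_CONTRASTS = (60.0, 80.0)


@dataclass
class ContrastResult:
    """Per-neuron contrast-response summary."""

    contrasts: np.ndarray
    rc: np.ndarray                      # pooled over states
    rc_by_state: dict = field(default_factory=dict)  # "stationary"/"running"
    blank_response: float | None = None
    ccom: float | None = None
    preference_class: str | None = None


def label_trial_state(speed, schedule: StimulusSchedule, rate: float = 30.0,
                      threshold: float = 1.0) -> np.ndarray:
    """Per-trial state from mean speed over the grating window.

    Returns an array of "stationary"/"running"; a mean speed of exactly
    ``threshold`` is stationary.
    """
    speed = np.asarray(speed, dtype=float)
    labels = []
    for t, row in enumerate(schedule.trials.itertuples(index=False)):
        a = int(np.floor(row.stim_on_s * rate))
        b = int(np.floor(row.stim_off_s * rate))
        if a < 0 or b > speed.size or a >= b:
            raise InvalidScheduleError(f"trial {t} window outside speed trace")
        labels.append("running" if speed[a:b].mean() > threshold
                      else "stationary")
    return np.array(labels)


def _rc(responses: np.ndarray, contrasts: np.ndarray,
        levels: np.ndarray) -> np.ndarray:
    out = np.full(levels.size, np.nan)
    for i, c in enumerate(levels):
        sel = contrasts == c
        if sel.any():
            out[i] = responses[sel].mean()
    return out


def contrast_curve(table: TrialResponseTable, neuron: int,
                   by_state: bool = False) -> ContrastResult:
    """Mean response at each contrast, pooling orientations.

    The caller is expected to have applied the responsiveness filter.
    With ``by_state=True`` the table's ``trials`` frame must carry a
    ``state`` column (see :func:`label_trial_state`); contrasts with no
    trial in a state are NaN with a warning.
    """
    trials = table.trials
    resp = table.responses[neuron]
    blank = trials["blank"].to_numpy()
    contrasts = trials["contrast_pct"].to_numpy(dtype=float)
    levels = np.unique(contrasts[~blank])
    result = ContrastResult(
        contrasts=levels,
        rc=_rc(resp[~blank], contrasts[~blank], levels),
        blank_response=float(resp[blank].mean()) if blank.any() else None,
    )
    if by_state:
        if "state" not in trials.columns:
            raise InvalidArgumentError(
                "by_state requires a 'state' trial column; run label_trial_state"
            )
        states = trials["state"].to_numpy()
        for s in ("stationary", "running"):
            sel = ~blank & (states == s)
            curve = _rc(resp[sel], contrasts[sel], levels)
            if np.isnan(curve).any():
                warnings.warn(f"some contrasts have no {s} trials")
            result.rc_by_state[s] = curve
    return result


def ccom(rc, contrasts) -> float:
    """Log-scale center of mass of the contrast-response curve.

    ``exp( sum max(Rc, 0) ln c / sum max(Rc, 0) )``; contrasts must be
    positive (blanks excluded upstream).
    """
    rc = np.asarray(rc, dtype=float)
    c = np.asarray(contrasts, dtype=float)
    if c.size < 2:
        raise InvalidArgumentError("need >= 2 contrasts")
    if np.any(c <= 0):
        raise InvalidArgumentError("contrasts must be > 0 (exclude blanks)")
    w = np.clip(rc, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise UndefinedCCOMError("all contrast-response weights <= 0")
    return float(np.exp(np.sum(w * np.log(c)) / total))


def preference_class(rc, contrasts) -> str:
    """Classify by preferred (argmax) contrast: low / high / other.

    Ties broken toward the lower contrast; NaN entries abort
    classification.
    """
    rc = np.asarray(rc, dtype=float)
    c = np.asarray(contrasts, dtype=float)
    if np.isnan(rc).any():
        raise InvalidArgumentError("undefined Rc entries; classification skipped")
    order = np.argsort(c)  # ensures argmax ties resolve to the lower contrast
    pref = c[order][int(np.argmax(rc[order]))]
    if pref in LOW_CONTRASTS:
        return "low"
    if pref in HIGH_CONTRASTS:
        return "high"
    return "other"


def contrast_analysis(table: TrialResponseTable, by_state: bool = True
                      ) -> list[ContrastResult]:
    """Contrast curve, blank response, cCOM and class for every neuron."""
    out = []
    for n in range(table.n_neurons):
        res = contrast_curve(table, n, by_state=by_state)
        try:
            res.ccom = ccom(res.rc, res.contrasts)
        except UndefinedCCOMError:
            warnings.warn(f"neuron {n}: cCOM undefined (nonpositive curve)")
        try:
            res.preference_class = preference_class(res.rc, res.contrasts)
        except InvalidArgumentError:
            pass
        out.append(res)
    return out
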