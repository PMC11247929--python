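"""Ground-truth-parameterized synthetic sessions.

Forward model for one neuron's event rate (events/s) at frame t:

    rate(t) = baseline_rate * gain_state(t) + speed_coupling * speed(t)
              + visual_gain * tuning(theta_t) * contrast_response(c_t)

where ``gain_state`` is ``run_gain`` in running frames (speed > 1 cm/s) and
1 otherwise, ``tuning`` is a von Mises bump on the doubled orientation
angle (period 180 deg, peak 1 at the preferred orientation, optionally
sharpened toward the preferred *direction*), and ``contrast_response`` is a
Naka-Rushton saturating curve ``c^n / (c^n + c50^n)`` or its reflection for
contrast-suppressed neurons.  The visual term applies only inside grating
windows and is zero on blank trials.

Events are Poisson-sampled per frame and convolved with a single-
exponential calcium kernel (decay ``tau_s``); somatic fluorescence adds a
positive offset, a scaled copy of a shared low-pass neuropil signal, and
white Gaussian noise.  All randomness flows through one
``numpy.random.Generator`` per call, so a fixed seed reproduces every
output bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .errors import InvalidArgumentError

__all__ = [
    "GroundTruthNeuron",
    "LocomotionBouts",
    "RawRecording",
    "StimulusSchedule",
    "TracedCellSpec",
    "gen_locomotion",
    "gen_pupil_with_blinks",
    "gen_recording",
    "gen_traced_cells",
    "default_traced_spec",
    "CONTRAST_LEVELS",
]

#: Grating contrasts used in the contrast-tuning protocol (%).
CONTRAST_LEVELS = (5.0, 10.0, 20.0, 40.0, 60.0, 80.0)


@dataclass
class GroundTruthNeuron:
    """Generative parameters for one simulated neuron.

    Rates are in events/s; ``run_gain`` multiplies the baseline during
    running (1 = no state modulation); ``speed_coupling`` adds
    events/s per cm/s of locomotion speed; ``tuning_concentration`` is the
    von Mises kappa on the doubled orientation angle; ``contrast_c50`` and
    ``contrast_exponent`` parameterize the Naka-Rushton contrast response
    whose direction is set by ``contrast_sign``; ``neuropil_weight`` is the
    fraction of the shared neuropil signal mixed into the somatic ROI.
    ``direction_gain`` (0 = none) adds a direction asymmetry so the two
    drifting directions of the preferred orientation differ, giving a
    nonzero DSI.
    """

    id: int
    baseline_rate: float = 0.1
    run_gain: float = 1.0
    speed_coupling: float = 0.0
    pref_orientation: float = 0.0
    tuning_concentration: float = 2.0
    contrast_c50: float = 20.0
    contrast_exponent: float = 2.0
    contrast_sign: str = "flat"
    visual_gain: float = 0.0
    noise_sd: float = 0.1
    neuropil_weight: float = 0.7
    direction_gain: float = 0.0

    def __post_init__(self):
        if self.baseline_rate < 0 or self.run_gain < 0 or self.speed_coupling < 0:
            raise InvalidArgumentError("rates and gains must be nonnegative")
        if not 0 <= self.pref_orientation < 360:
            raise InvalidArgumentError("pref_orientation must be in [0, 360)")
        if self.tuning_concentration < 0:
            raise InvalidArgumentError("tuning_concentration must be >= 0")
        if not 0 < self.contrast_c50 <= 100:
            raise InvalidArgumentError("contrast_c50 must be in (0, 100]")
        if self.contrast_exponent <= 0:
            raise InvalidArgumentError("contrast_exponent must be > 0")
        if self.contrast_sign not in ("increasing", "decreasing", "flat"):
            raise InvalidArgumentError(f"bad contrast_sign {self.contrast_sign!r}")
        if self.visual_gain < 0:
            raise InvalidArgumentError("visual_gain must be >= 0")
        if not 0 <= self.neuropil_weight < 1:
            raise InvalidArgumentError("neuropil_weight must be in [0, 1)")

    def tuning(self, orientation_deg: float) -> float:
        """Orientation tuning factor in [0, 1], peak at pref_orientation."""
        delta = math.radians(orientation_deg - self.pref_orientation)
        kappa = self.tuning_concentration
        ori = math.exp(kappa * (math.cos(2 * delta) - 1.0))
        if self.direction_gain > 0:
            ori *= (1.0 + self.direction_gain * math.cos(delta)) / (
                1.0 + self.direction_gain
            )
        return ori

    def contrast_response(self, contrast_pct: float) -> float:
        """Naka-Rushton contrast factor in [0, 1]; 0 on blank (0%) trials."""
        if contrast_pct <= 0:
            return 0.0
        n = self.contrast_exponent
        cn = contrast_pct ** n
        nr = cn / (cn + self.contrast_c50 ** n)
        if self.contrast_sign == "decreasing":
            return 1.0 - nr
        if self.contrast_sign == "flat":
            return 1.0
        return nr


@dataclass
class LocomotionBouts:
    """Two-state semi-Markov locomotion parameters.

    Bout durations are exponential with the given means; after each
    stationary bout a run bout starts with probability ``run_prob``.  Run
    speed is lognormal around ``speed_median_cm_s`` (per-bout level) with
    fast within-bout jitter.
    """

    stationary_mean_s: float = 20.0
    run_mean_s: float = 10.0
    run_prob: float = 1.0
    speed_median_cm_s: float = 5.0
    speed_sigma: float = 0.4
    jitter_sd_cm_s: float = 0.3

    def __post_init__(self):
        if self.stationary_mean_s <= 0 or self.run_mean_s <= 0:
            raise InvalidArgumentError("bout mean durations must be positive")
        if not 0 <= self.run_prob <= 1:
            raise InvalidArgumentError("run_prob must be in [0, 1]")


def gen_locomotion(duration_s: float, frame_rate: float = 30.0,
                   bouts: LocomotionBouts | None = None, seed: int = 0):
    """Simulate a nonnegative locomotion speed trace (cm/s).

    Alternates stationary (~0 cm/s) and running bouts; length is
    ``round(duration_s * frame_rate)`` samples.
    """
    if duration_s <= 0 or frame_rate <= 0:
        raise InvalidArgumentError("duration_s and frame_rate must be positive")
    bouts = bouts or LocomotionBouts()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * frame_rate))
    speed = np.zeros(n)
    t = 0
    running = False
    while t < n:
        if running:
            dur = rng.exponential(bouts.run_mean_s)
            n_b = max(1, int(round(dur * frame_rate)))
            level = bouts.speed_median_cm_s * math.exp(
                rng.normal(0.0, bouts.speed_sigma)
            )
            seg = level + rng.normal(0.0, bouts.jitter_sd_cm_s, size=min(n_b, n - t))
            speed[t:t + n_b] = seg
            running = False
        else:
            dur = rng.exponential(bouts.stationary_mean_s)
            n_b = max(1, int(round(dur * frame_rate)))
            seg = np.abs(rng.normal(0.0, 0.02, size=min(n_b, n - t)))
            speed[t:t + n_b] = seg
            running = rng.random() < bouts.run_prob
        t += n_b
    # short ramps at transitions, as a wheel has inertia
    speed = gaussian_filter1d(speed, sigma=0.1 * frame_rate)
    return np.clip(speed, 0.0, None)


def gen_pupil_with_blinks(duration_s: float, rate_hz: float = 19.06,
                          blink_rate_per_min: float = 2.0, seed: int = 0,
                          blink_duration_s: tuple[float, float] = (0.15, 0.4),
                          blink_depth: float = 4.0):
    """Simulate a z-scale pupil trace with square blink dropouts.

    Returns ``(trace, intervals)`` where ``intervals`` is the ground-truth
    list of (onset_s, offset_s) blink windows, for validating detection.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise InvalidArgumentError("duration_s and rate_hz must be positive")
    if blink_rate_per_min < 0:
        raise InvalidArgumentError("blink rate must be nonnegative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    latent = gaussian_filter1d(rng.standard_normal(n), sigma=2.0 * rate_hz)
    latent = latent / max(np.std(latent), 1e-12)

    n_blinks = rng.poisson(blink_rate_per_min * duration_s / 60.0)
    onsets = np.sort(rng.uniform(0.5, max(0.6, duration_s - 1.0), size=n_blinks))
    durations = rng.uniform(*blink_duration_s, size=n_blinks)
    intervals: list[tuple[float, float]] = []
    for on, d in zip(onsets, durations):
        off = min(on + d, duration_s - 1.0 / rate_hz)
        if intervals and on <= intervals[-1][1] + 0.5:
            continue  # keep ground-truth blinks well separated
        intervals.append((float(on), float(off)))
    trace = latent.copy()
    t = np.arange(n) / rate_hz
    for on, off in intervals:
        trace[(t >= on) & (t <= off)] -= blink_depth
    return trace, intervals


@dataclass
class StimulusSchedule:
    """Ordered trial records for one session.

    ``trials`` columns: trial_start_s, stim_on_s, stim_off_s,
    orientation_deg (NaN on blanks/spontaneous), contrast_pct (0 on
    blanks), blank (bool).  ``protocol`` is one of spontaneous /
    orientation / contrast.
    """

    trials: pd.DataFrame
    protocol: str
    duration_s: float

    def __post_init__(self):
        if self.protocol not in ("spontaneous", "orientation", "contrast"):
            raise InvalidArgumentError(f"unknown protocol {self.protocol!r}")
        df = self.trials
        if len(df):
            if not (df["stim_on_s"] < df["stim_off_s"]).all():
                raise InvalidArgumentError("stim_on must precede stim_off")
            starts = df["trial_start_s"].to_numpy()
            if np.any(np.diff(starts) <= 0):
                raise InvalidArgumentError("trials must be time-ordered")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @classmethod
    def spontaneous(cls, duration_s: float = 730.0) -> "StimulusSchedule":
        """Gray-screen session with no trials (~730 s in the study design)."""
        cols = ["trial_start_s", "stim_on_s", "stim_off_s", "orientation_deg",
                "contrast_pct", "blank"]
        return cls(pd.DataFrame(columns=cols), "spontaneous", duration_s)

    @classmethod
    def orientation(cls, n_repeats: int = 10, seed: int = 0,
                    contrast_pct: float = 80.0,
                    pre_s: float = 10.0) -> "StimulusSchedule":
        """Orientation-tuning protocol.

        6 s trials (1 s gray, 2 s grating, 3 s gray), 12 orientations
        30 deg apart in randomized order, ``n_repeats`` repeats each,
        after a ``pre_s`` gray baseline.
        """
        rng = np.random.default_rng(seed)
        oris = np.repeat(np.arange(12) * 30.0, n_repeats)
        rng.shuffle(oris)
        start = pre_s + 6.0 * np.arange(oris.size)
        df = pd.DataFrame({
            "trial_start_s": start,
            "stim_on_s": start + 1.0,
            "stim_off_s": start + 3.0,
            "orientation_deg": oris,
            "contrast_pct": contrast_pct,
            "blank": False,
        })
        return cls(df, "orientation", float(start[-1] + 6.0 + 2.0))

    @classmethod
    def contrast(cls, n_repeats: int = 15, seed: int = 0,
                 pre_s: float = 10.0,
                 blank_every: int = 20) -> "StimulusSchedule":
        """Contrast-tuning protocol.

        3 s trials (0.8 s gray, 2 s grating, 0.2 s gray); 6 contrasts x
        8 orientations (45 deg apart) x ``n_repeats``, randomized, with one
        blank trial randomly placed in every ``blank_every`` trials.
        """
        rng = np.random.default_rng(seed)
        conds = [(c, o) for c in CONTRAST_LEVELS for o in np.arange(8) * 45.0
                 for _ in range(n_repeats)]
        rng.shuffle(conds)
        trials: list[tuple[float, float, bool]] = [
            (c, o, False) for c, o in conds
        ]
        n_blanks = len(conds) // blank_every
        for _ in range(n_blanks):
            pos = int(rng.integers(0, len(trials) + 1))
            trials.insert(pos, (0.0, np.nan, True))
        start = pre_s + 3.0 * np.arange(len(trials))
        df = pd.DataFrame({
            "trial_start_s": start,
            "stim_on_s": start + 0.8,
            "stim_off_s": start + 2.8,
            "orientation_deg": [o for _, o, _ in trials],
            "contrast_pct": [c for c, _, _ in trials],
            "blank": [b for _, _, b in trials],
        })
        return cls(df, "contrast", float(start[-1] + 3.0 + 2.0))


@dataclass
class RawRecording:
    """Simulated raw fluorescence for one session (neurons x frames)."""

    frame_rate: float
    f_soma: np.ndarray
    f_neuropil: np.ndarray
    indicator: str = "GCaMP7s"
    ground_truth: list[GroundTruthNeuron] | None = None
    seed: int = 0
    event_rate: np.ndarray | None = None  # ground-truth rate, events/s

    def __post_init__(self):
        self.f_soma = np.asarray(self.f_soma, dtype=float)
        self.f_neuropil = np.asarray(self.f_neuropil, dtype=float)
        if self.f_soma.shape != self.f_neuropil.shape:
            raise InvalidArgumentError("f_soma and f_neuropil shapes differ")
        if not (np.all(np.isfinite(self.f_soma))
                and np.all(np.isfinite(self.f_neuropil))):
            raise InvalidArgumentError("fluorescence contains non-finite values")


def _stimulus_drive(neurons, schedule: StimulusSchedule, n_frames: int,
                    frame_rate: float) -> np.ndarray:
    """(neurons x frames) visual rate factor: tuning x contrast response."""
    drive = np.zeros((len(neurons), n_frames))
    for row in schedule.trials.itertuples(index=False):
        if row.blank:
            continue
        a = int(np.floor(row.stim_on_s * frame_rate))
        b = int(np.floor(row.stim_off_s * frame_rate))
        for i, nrn in enumerate(neurons):
            drive[i, a:b] = (
                nrn.tuning(row.orientation_deg)
                * nrn.contrast_response(row.contrast_pct)
            )
    return drive


def gen_recording(neurons: list[GroundTruthNeuron], schedule: StimulusSchedule,
                  speed: np.ndarray, frame_rate: float = 30.0, seed: int = 0,
                  indicator: str = "GCaMP7s", tau_s: float = 1.0,
                  event_amplitude: float = 0.2, f_offset: float = 1.0,
                  neuropil_baseline: float = 1.0,
                  neuropil_sd: float = 0.05,
                  run_threshold: float = 1.0) -> RawRecording:
    """Simulate somatic + neuropil fluorescence from the forward model."""
    speed = np.asarray(speed, dtype=float)
    n_frames = speed.size
    if schedule.duration_s * frame_rate > n_frames + 0.5:
        raise InvalidArgumentError(
            f"schedule ({schedule.duration_s}s) extends past the speed trace "
            f"({n_frames / frame_rate:.1f}s)"
        )
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    running = speed > run_threshold

    gains = np.array([n.run_gain for n in neurons])
    base = np.array([n.baseline_rate for n in neurons])
    coup = np.array([n.speed_coupling for n in neurons])
    vis = np.array([n.visual_gain for n in neurons])

    state_gain = np.where(running[None, :], gains[:, None], 1.0)
    rate = base[:, None] * state_gain + coup[:, None] * speed[None, :]
    rate = rate + vis[:, None] * _stimulus_drive(neurons, schedule, n_frames,
                                                 frame_rate)

    events = rng.poisson(rate * dt).astype(float)
    decay = math.exp(-dt / tau_s)
    signal = lfilter([event_amplitude], [1.0, -decay], events, axis=1)

    common = gaussian_filter1d(rng.standard_normal(n_frames),
                               sigma=0.5 * frame_rate)
    common = common / max(np.std(common), 1e-12) * neuropil_sd
    f_neuropil = np.tile(neuropil_baseline + common, (len(neurons), 1))

    weights = np.array([n.neuropil_weight for n in neurons])
    noise_sd = np.array([n.noise_sd for n in neurons])
    noise = rng.standard_normal((len(neurons), n_frames)) * noise_sd[:, None]
    f_soma = f_offset + signal + weights[:, None] * f_neuropil + noise

    return RawRecording(frame_rate=frame_rate, f_soma=f_soma,
                        f_neuropil=f_neuropil, indicator=indicator,
                        ground_truth=list(neurons), seed=seed,
                        event_rate=rate)


@dataclass
class TracedCellSpec:
    """Multinomial description of a rabies-tracing experiment.

    ``region_probs`` maps atlas region acronyms to input-cell
    probabilities; ``layer_probs`` maps region -> layer distribution
    (regions absent default to layer "none"); ``ipsi_fraction`` maps
    region -> probability of the ipsilateral hemisphere (default 1).
    """

    region_probs: dict[str, float]
    n_inputs: int = 1000
    n_starters: int = 30
    layer_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    ipsi_fraction: dict[str, float] = field(default_factory=dict)
    starter_layer_probs: dict[str, float] = field(
        default_factory=lambda: {"L1": 0.2, "L2/3": 0.3, "L4": 0.15,
                                 "L5": 0.25, "L6": 0.1})
    starter_region: str = "VISp"

    def __post_init__(self):
        if not self.region_probs:
            raise InvalidArgumentError("region_probs must be non-empty")
        for name, probs in [("region_probs", self.region_probs),
                            ("starter_layer_probs", self.starter_layer_probs),
                            *[(f"layer_probs[{k}]", v)
                              for k, v in self.layer_probs.items()]]:
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidArgumentError(f"{name} sums to {total}, not 1")
        if self.n_inputs < 0 or self.n_starters < 0:
            raise InvalidArgumentError("counts must be nonnegative")


def default_traced_spec(n_inputs: int = 1000, n_starters: int = 30) -> TracedCellSpec:
    """A plausible V1 interneuron input distribution for simulations.

    Dominated by local V1 (VISp) with long-range cortical (RSP, TEa, ORB,
    higher visual areas, ACA) and thalamic (LGd, LP, LD) inputs.
    """
    regions = {
        "VISp": 0.55, "VISl": 0.05, "VISal": 0.03, "RSP": 0.08, "TEa": 0.03,
        "ORB": 0.015, "ACA": 0.02, "CLA": 0.015, "LGd": 0.12, "LP": 0.06,
        "LD": 0.01, "HPF": 0.02,
    }
    layer_probs = {
        "VISp": {"L1": 0.05, "L2/3": 0.40, "L4": 0.20, "L5": 0.25, "L6": 0.10},
        "RSP": {"L2/3": 0.3, "L5": 0.5, "L6": 0.2},
    }
    ipsi = {r: 1.0 for r in regions}
    ipsi["VISp"] = 0.95
    ipsi["RSP"] = 0.9
    return TracedCellSpec(region_probs=regions, n_inputs=n_inputs,
                          n_starters=n_starters, layer_probs=layer_probs,
                          ipsi_fraction=ipsi)


def gen_traced_cells(spec: TracedCellSpec, seed: int = 0) -> pd.DataFrame:
    """Sample a traced-cell table (one row per detected cell).

    Columns: cell_id, region, hemisphere {ipsi, contra}, layer
    {L1, L2/3, L4, L5, L6, none}, gfp {0, 1}, mcherry {0, 1}.  Input cells
    are mCherry+ GFP-; starters are mCherry+ GFP+ in the starter region.
    """
    rng = np.random.default_rng(seed)
    regions = list(spec.region_probs)
    probs = np.array([spec.region_probs[r] for r in regions])
    rows = []
    region_draws = rng.choice(len(regions), size=spec.n_inputs, p=probs)
    for i, ridx in enumerate(region_draws):
        region = regions[ridx]
        lp = spec.layer_probs.get(region, {"none": 1.0})
        layers = list(lp)
        layer = layers[rng.choice(len(layers), p=np.array(list(lp.values())))]
        p_ipsi = spec.ipsi_fraction.get(region, 1.0)
        hemi = "ipsi" if rng.random() < p_ipsi else "contra"
        rows.append((i, region, hemi, layer, 0, 1))
    slp = spec.starter_layer_probs
    slayers = list(slp)
    for j in range(spec.n_starters):
        layer = slayers[rng.choice(len(slayers), p=np.array(list(slp.values())))]
        rows.append((spec.n_inputs + j, spec.starter_region, "ipsi", layer, 1, 1))
    return pd.DataFrame(rows, columns=["cell_id", "region", "hemisphere",
                                       "layer", "gfp", "mcherry"])
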