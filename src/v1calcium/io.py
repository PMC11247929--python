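"""HDF5 session container and protocol orchestration.

One self-describing HDF5 file per session:

    /fluorescence   f_soma, f_neuropil      (attrs: frame_rate, indicator)
    /behavior       speed [, pupil, blink]  (attrs: speed_rate, pupil_rate)
    /schedule       one dataset per trial column (attrs: protocol, duration_s)
    /ground_truth   optional generator parameters, one dataset per field
    /processed      standardized_dff, included (attrs: config_hash, ...)
    /results        per-protocol arrays (attrs: config_hash, seed)

All trial windows are half-open [on, off) in seconds and converted to
frames by floor(on * rate) ... floor(off * rate).  Result tables are also
emitted as CSV/JSON next to the container so downstream statistics can be
run without HDF5 tooling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import contrast as ct
from . import preprocess as pp
from . import state as st
from . import tuning as tn
from .errors import SchemaError
from .synthetic import GroundTruthNeuron, RawRecording, StimulusSchedule

__all__ = [
    "SCHEMA_VERSION",
    "DEFAULT_CONFIG",
    "load_config",
    "config_hash",
    "save_session",
    "load_session",
    "run_protocol",
]

SCHEMA_VERSION = "1"

#: Every tunable named in the module design decisions, in one place.
DEFAULT_CONFIG: dict = {
    "neuropil_r": None,          # None -> derived from the indicator label
    "baseline_window_s": 150.0,
    "baseline_percentile": 30.0,
    "inclusion_threshold": 3.0,
    "run_threshold_cm_s": 1.0,
    "alpha": 0.05,
    "n_shuffles": 1000,
    "max_lag_s": 10.0,
    "shuffle_null": "permutation",   # or "circular"
    "trial_baseline_s": 0.5,
    "responsive_k": 3.0,
    "responsive_min_trials": 2,
    "blink_smooth_window_s": 0.26,
    "blink_vel_threshold": 5.0,
    "blink_buffer_s": 0.1,
    "blink_merge_gap_s": 0.3,
    "leading_samples_dropped": 0,
    "preference_rule": "argmax",     # or "ccom_band"
    "n_boot": 10000,
}

_TRIAL_COLS = ["trial_start_s", "stim_on_s", "stim_off_s", "orientation_deg",
               "contrast_pct", "blank"]


def load_config(path=None) -> dict:
    """DEFAULT_CONFIG overridden by a YAML file (unknown keys rejected)."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_session(path, recording: RawRecording, schedule: StimulusSchedule,
                 speed=None, speed_rate: float = 30.0, pupil=None,
                 pupil_rate: float = 19.06, blink=None) -> None:
    """Write a raw session container (fluorescence + behavior + schedule)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["seed"] = recording.seed
        fl = f.create_group("fluorescence")
        fl.create_dataset("f_soma", data=recording.f_soma)
        fl.create_dataset("f_neuropil", data=recording.f_neuropil)
        fl.attrs["frame_rate"] = recording.frame_rate
        fl.attrs["indicator"] = recording.indicator

        bg = f.create_group("behavior")
        if speed is not None:
            bg.create_dataset("speed", data=np.asarray(speed, dtype=float))
            bg.attrs["speed_rate"] = speed_rate
        if pupil is not None:
            bg.create_dataset("pupil", data=np.asarray(pupil, dtype=float))
            bg.attrs["pupil_rate"] = pupil_rate
        if blink is not None:
            bg.create_dataset("blink", data=np.asarray(blink, dtype=float))
            bg.attrs["pupil_rate"] = pupil_rate

        sg = f.create_group("schedule")
        sg.attrs["protocol"] = schedule.protocol
        sg.attrs["duration_s"] = schedule.duration_s
        for col in _TRIAL_COLS:
            data = schedule.trials[col].to_numpy() if len(schedule.trials) \
                else np.array([])
            sg.create_dataset(col, data=np.asarray(data, dtype=float))

        if recording.ground_truth:
            gt = f.create_group("ground_truth")
            fields = [fld.name for fld in
                      dataclasses.fields(GroundTruthNeuron)
                      if fld.name != "contrast_sign"]
            for name in fields:
                gt.create_dataset(name, data=np.array(
                    [getattr(n, name) for n in recording.ground_truth],
                    dtype=float))
            gt.create_dataset("contrast_sign", data=np.array(
                [n.contrast_sign for n in recording.ground_truth], dtype="S"))


def load_session(path):
    """Read a session container -> (recording, schedule, behavior dict)."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version {f.attrs.get('schema_version')!r} != "
                f"{SCHEMA_VERSION!r}"
            )
        if "fluorescence" not in f:
            raise SchemaError("missing group /fluorescence")
        fl = f["fluorescence"]
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            n = g["id"].shape[0]
            gt = []
            for i in range(n):
                kwargs = {name: g[name][i] for name in g
                          if name != "contrast_sign"}
                kwargs["id"] = int(kwargs["id"])
                kwargs["contrast_sign"] = g["contrast_sign"][i].decode()
                gt.append(GroundTruthNeuron(**kwargs))
        recording = RawRecording(
            frame_rate=float(fl.attrs["frame_rate"]),
            f_soma=fl["f_soma"][()],
            f_neuropil=fl["f_neuropil"][()],
            indicator=str(fl.attrs["indicator"]),
            ground_truth=gt,
            seed=int(f.attrs.get("seed", 0)),
        )
        sg = f["schedule"]
        trials = pd.DataFrame({c: sg[c][()] for c in _TRIAL_COLS})
        trials["blank"] = trials["blank"].astype(bool)
        schedule = StimulusSchedule(trials, str(sg.attrs["protocol"]),
                                    float(sg.attrs["duration_s"]))
        behavior = {}
        if "behavior" in f:
            bg = f["behavior"]
            for key in ("speed", "pupil", "blink"):
                if key in bg:
                    behavior[key] = bg[key][()]
            behavior["speed_rate"] = float(bg.attrs.get("speed_rate", 30.0))
            behavior["pupil_rate"] = float(bg.attrs.get("pupil_rate", 19.06))
    return recording, schedule, behavior


def _write_processed(path, activity: pp.ActivityMatrix, cfg: dict,
                     overwrite: bool) -> None:
    with h5py.File(path, "a") as f:
        if "processed" in f:
            if not overwrite:
                raise SchemaError("processed group exists; pass overwrite")
            del f["processed"]
        g = f.create_group("processed")
        g.create_dataset("standardized_dff", data=activity.values)
        g.create_dataset("included", data=activity.included)
        g.attrs["frame_rate"] = activity.frame_rate
        g.attrs["config_hash"] = config_hash(cfg)


def preprocess_session(path, cfg: dict | None = None,
                       overwrite: bool = True) -> pp.ActivityMatrix:
    """Neuropil-correct, baseline, dF/F0 and standardize a session in place."""
    cfg = cfg or dict(DEFAULT_CONFIG)
    recording, _, _ = load_session(path)
    r = cfg["neuropil_r"]
    if r is None:
        r = pp.neuropil_factor(recording.indicator)
    activity = pp.preprocess_traces(
        recording.f_soma, recording.f_neuropil, recording.frame_rate, r=r,
        window_s=cfg["baseline_window_s"],
        percentile=cfg["baseline_percentile"],
        inclusion_threshold=cfg["inclusion_threshold"],
    )
    _write_processed(path, activity, cfg, overwrite)
    return activity


def _load_processed(path) -> pp.ActivityMatrix:
    with h5py.File(path, "r") as f:
        if "processed" not in f:
            raise SchemaError("missing group /processed; run preprocess first")
        g = f["processed"]
        return pp.ActivityMatrix(values=g["standardized_dff"][()],
                                 frame_rate=float(g.attrs["frame_rate"]),
                                 included=g["included"][()])


def behavior_session(path, cfg: dict | None = None) -> beh.BehaviorTraces:
    """Condition the behavior group: blink detection + pupil interpolation."""
    cfg = cfg or dict(DEFAULT_CONFIG)
    _, _, behavior = load_session(path)
    if "speed" not in behavior:
        raise SchemaError("missing /behavior/speed")
    speed = behavior["speed"]
    drop = int(cfg["leading_samples_dropped"])
    pupil = behavior.get("pupil")
    blink = behavior.get("blink", pupil)
    intervals: list[tuple[float, float]] = []
    pupil_filled = None
    if pupil is not None:
        rate = behavior["pupil_rate"]
        pupil = pupil[drop:]
        blink = blink[drop:]
        intervals = beh.detect_blinks(
            beh.zscore(blink), rate,
            smooth_window_s=cfg["blink_smooth_window_s"],
            vel_threshold=cfg["blink_vel_threshold"],
            buffer_s=cfg["blink_buffer_s"],
            merge_gap_s=cfg["blink_merge_gap_s"],
        )
        pupil_filled = beh.interpolate_pupil(
            beh.zscore(pupil), intervals, rate).values
    return beh.BehaviorTraces(speed=speed, speed_rate=behavior["speed_rate"],
                              pupil_z=pupil_filled,
                              pupil_rate=behavior.get("pupil_rate", 19.06),
                              blink_intervals=intervals)


def _json_dump(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_protocol(path, protocol: str | None = None, seed: int = 0,
                 cfg: dict | None = None, out_dir=None,
                 overwrite: bool = True) -> dict:
    """Run the full stage chain for a session and emit result artifacts.

    spontaneous: preprocess -> behavior -> state dynamics (per-neuron
    speed coupling, pairwise synchrony); orientation: ... -> tuning
    statistics; contrast: ... -> contrast statistics.  Deterministic for
    fixed config and seed.  Returns the summary dict written to JSON.
    """
    cfg = cfg or dict(DEFAULT_CONFIG)
    path = Path(path)
    out_dir = Path(out_dir) if out_dir else path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    _, schedule, behavior = load_session(path)
    protocol = protocol or schedule.protocol
    activity = preprocess_session(path, cfg, overwrite=overwrite)
    stem = path.stem
    summary: dict = {"protocol": protocol, "seed": seed,
                     "config_hash": config_hash(cfg),
                     "n_neurons": activity.n_neurons,
                     "n_included": int(activity.included.sum())}

    if protocol == "spontaneous":
        if "speed" not in behavior:
            raise SchemaError("missing /behavior/speed for spontaneous protocol")
        speed = behavior["speed"]
        labels = st.classify_frames(speed, cfg["run_threshold_cm_s"])
        means = st.state_means(activity, labels)
        inc = np.flatnonzero(activity.included)
        act5 = pp.resample_5hz(activity.values[inc], activity.frame_rate)
        speed5 = pp.resample_5hz(speed, behavior["speed_rate"])
        rows = []
        for k, n in enumerate(inc):
            res = st.xcorr_speed(act5[k], speed5, max_lag_s=cfg["max_lag_s"],
                                 n_shuffles=cfg["n_shuffles"],
                                 alpha=cfg["alpha"], seed=seed + int(n),
                                 null=cfg["shuffle_null"])
            rows.append((int(n), res.r_zero, res.p, res.significant,
                         res.peak_r, res.peak_lag_s))
        xcorr_df = pd.DataFrame(rows, columns=["roi_id", "r_zero", "p",
                                               "significant", "peak_r",
                                               "peak_lag_s"])
        neuron_df = means.merge(xcorr_df, on="roi_id", how="left")
        pairs = st.pairwise_synchrony(act5, n_shuffles=cfg["n_shuffles"],
                                      alpha=cfg["alpha"], seed=seed,
                                      null=cfg["shuffle_null"])
        neuron_df.to_csv(out_dir / f"{stem}_neurons.csv", index=False)
        pairs.to_csv(out_dir / f"{stem}_pairs.csv", index=False)
        summary.update(st.synchrony_summary(pairs))
        summary["frac_speed_significant"] = float(xcorr_df["significant"].mean())
        summary["mean_r_speed"] = float(xcorr_df["r_zero"].mean())

    elif protocol == "orientation":
        table = tn.extract_trial_responses(activity, schedule,
                                           cfg["trial_baseline_s"])
        results = tn.orientation_analysis(table, k=cfg["responsive_k"],
                                          min_trials=cfg["responsive_min_trials"])
        rows = []
        for n, res in enumerate(results):
            if res is None:
                continue
            rows.append((int(activity.roi_ids[n]), res.responsive,
                         res.preferred_orientation, res.gosi, res.dsi, res.snr))
        neuron_df = pd.DataFrame(rows, columns=["roi_id", "responsive",
                                                "pref_orientation", "gosi",
                                                "dsi", "snr"])
        resp_idx = [n for n, r in enumerate(results)
                    if r is not None and r.responsive]
        pair_rows = []
        for ai in range(len(resp_idx)):
            for bi in range(ai + 1, len(resp_idx)):
                j, k = resp_idx[ai], resp_idx[bi]
                _, mj = table.repetition_matrix(j)
                _, mk = table.repetition_matrix(k)
                pair_rows.append((j, k,
                                  tn.signal_correlation(mj, mk, seed=seed),
                                  tn.noise_correlation(mj, mk)))
        pairs_df = pd.DataFrame(pair_rows, columns=["i", "j", "rho_signal",
                                                    "rho_noise"])
        neuron_df.to_csv(out_dir / f"{stem}_tuning.csv", index=False)
        pairs_df.to_csv(out_dir / f"{stem}_tuning_pairs.csv", index=False)
        summary["frac_responsive"] = float(neuron_df["responsive"].mean())
        summary["mean_gosi"] = float(neuron_df["gosi"].mean())
        summary["mean_dsi"] = float(neuron_df["dsi"].mean())
        summary["mean_snr"] = float(neuron_df["snr"].mean())

    elif protocol == "contrast":
        if "speed" not in behavior:
            raise SchemaError("missing /behavior/speed for contrast protocol")
        table = tn.extract_trial_responses(activity, schedule,
                                           cfg["trial_baseline_s"])
        table.trials["state"] = ct.label_trial_state(
            behavior["speed"], schedule, rate=behavior["speed_rate"],
            threshold=cfg["run_threshold_cm_s"])
        responsive = tn.responsive_mask(table, k=cfg["responsive_k"],
                                        min_trials=cfg["responsive_min_trials"])
        results = ct.contrast_analysis(table, by_state=True)
        rows = []
        for n, res in enumerate(results):
            row = {"roi_id": int(activity.roi_ids[n]),
                   "responsive": bool(responsive[n]),
                   "blank_response": res.blank_response,
                   "ccom": res.ccom,
                   "preference_class": res.preference_class}
            for c, v in zip(res.contrasts, res.rc):
                row[f"rc_{int(c)}"] = v
            for s, curve in res.rc_by_state.items():
                for c, v in zip(res.contrasts, curve):
                    row[f"rc_{int(c)}_{s}"] = v
            rows.append(row)
        neuron_df = pd.DataFrame(rows)
        neuron_df.to_csv(out_dir / f"{stem}_contrast.csv", index=False)
        resp = neuron_df[neuron_df["responsive"]]
        summary["frac_responsive"] = float(neuron_df["responsive"].mean())
        if len(resp):
            summary["mean_ccom"] = float(resp["ccom"].mean())
            counts = resp["preference_class"].value_counts()
            for cls in ("low", "high", "other"):
                summary[f"frac_{cls}"] = float(counts.get(cls, 0) / len(resp))
    else:
        raise SchemaError(f"unknown protocol {protocol!r}")

    with h5py.File(path, "a") as f:
        if "results" in f:
            if not overwrite:
                raise SchemaError("results group exists; pass overwrite")
            del f["results"]
        g = f.create_group("results")
        g.attrs["config_hash"] = config_hash(cfg)
        g.attrs["seed"] = seed
        g.attrs["protocol"] = protocol
    _json_dump(summary, out_dir / f"{stem}_summary.json")
    return summary
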