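"""Plain-text readers and writers for the pipeline's artifacts.

Spike trains travel as JSON (trial -> unit -> times) or long-format CSV;
torque as CSV (t_s, torque_nm, torque_pct_mvt); commands and ground truth as
JSON; EMG as a wide CSV matrix with a channel-map JSON giving each column's
grid row/col.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import TorqueTrace
from .simulate import CommandProfile, SpikeTrain


def write_spikes_json(trains, path):
    by_trial: dict = {}
    for tr in trains:
        by_trial.setdefault(tr.trial_id, {})[str(tr.unit_id)] = \
            np.asarray(tr.times).tolist()
    Path(path).write_text(json.dumps(by_trial))


def read_spikes_json(path):
    data = json.loads(Path(path).read_text())
    trains = []
    for trial_id, units in data.items():
        for uid, times in units.items():
            trains.append(SpikeTrain(unit_id=int(uid),
                                     times=np.asarray(times, float),
                                     trial_id=trial_id))
    return trains


def write_spikes_csv(trains, path):
    rows = [(tr.trial_id, tr.unit_id, t)
            for tr in trains for t in tr.times]
    pd.DataFrame(rows, columns=["trial_id", "unit_id", "spike_time_s"]) \
        .to_csv(path, index=False)


def read_spikes_csv(path):
    df = pd.read_csv(path)
    trains = []
    for (trial, uid), g in df.groupby(["trial_id", "unit_id"]):
        trains.append(SpikeTrain(unit_id=int(uid),
                                 times=np.sort(g["spike_time_s"].to_numpy()),
                                 trial_id=str(trial)))
    return trains


def write_torque_csv(trace: TorqueTrace, path):
    pd.DataFrame({"t_s": trace.t, "torque_nm": trace.torque_raw,
                  "torque_pct_mvt": trace.torque_pct}).to_csv(path,
                                                              index=False)


def read_torque_csv(path, mvt: float | None = None) -> TorqueTrace:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    raw = df["torque_nm"].to_numpy()
    if mvt is None:
        if "torque_pct_mvt" not in df.columns:
            raise ValueError("need mvt or a torque_pct_mvt column")
        pct = df["torque_pct_mvt"].to_numpy()
        scale = np.median(raw[np.abs(pct) > 1e-9]
                          / pct[np.abs(pct) > 1e-9]) if np.any(
                              np.abs(pct) > 1e-9) else 1.0
        mvt = float(100.0 * scale)
    return TorqueTrace.from_raw(t, raw, mvt=mvt, fs=fs)


def write_command_json(cmd: CommandProfile, path):
    Path(path).write_text(json.dumps({
        "protocol": cmd.protocol, "fs": cmd.fs,
        "breakpoints": [list(b) for b in cmd.breakpoints],
        "segments": {k: list(v) for k, v in cmd.segments.items()}}))


def read_command_json(path) -> CommandProfile:
    d = json.loads(Path(path).read_text())
    bps = tuple((float(a), float(b)) for a, b in d["breakpoints"])
    fs = float(d["fs"])
    t_end = bps[-1][0]
    t = np.arange(int(t_end * fs) + 1) / fs
    bt = np.array([b[0] for b in bps])
    bv = np.array([b[1] for b in bps])
    return CommandProfile(t=t, drive=np.interp(t, bt, bv),
                          segments={k: tuple(v)
                                    for k, v in d["segments"].items()},
                          breakpoints=bps, protocol=d["protocol"], fs=fs)


def write_truth_json(truth, path):
    Path(path).write_text(json.dumps({
        "thresholds": truth.thresholds.tolist(),
        "hysteresis_eff": truth.hysteresis_eff.tolist(),
        "gains": truth.gains.tolist(),
        "rate_min": truth.rate_min,
        "t_rec": truth.t_rec.tolist(),
        "t_derec": truth.t_derec.tolist(),
        "twitch_peak": truth.twitch_peak.tolist(),
        "twitch_tc": truth.twitch_tc.tolist(),
        "categories": truth.categories}))


def write_rates_csv(smoothed_by_unit: dict, path):
    """Smoothed discharge-rate curves as long-format CSV."""
    frames = [pd.DataFrame({"unit_id": uid, "t_s": sm.t, "rate_pps": sm.rate})
              for uid, sm in sorted(smoothed_by_unit.items())]
    out = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["unit_id", "t_s", "rate_pps"])
    out.to_csv(path, index=False)


def write_emg_csv(emg: np.ndarray, path, grid_shape=(13, 5)):
    """EMG matrix as one column per channel, plus a channel-map sidecar."""
    cols = [f"ch{i:02d}" for i in range(emg.shape[0])]
    pd.DataFrame(emg.T, columns=cols).to_csv(path, index=False)
    rows, ncol = grid_shape
    cmap = {f"ch{i:02d}": [i // ncol, i % ncol]
            for i in range(emg.shape[0])}
    Path(str(path) + ".channels.json").write_text(json.dumps(cmap))


def read_emg_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy().T
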