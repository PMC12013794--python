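"""Canned study-condition experiments on the synthetic pool.

Each function wires one of the package's standard validation experiments:
Delta-F parameter recovery on triangular ramps, noiseless classification and
sustained-discharge checks on sombreros, muscle-length (ankle-angle)
contrasts, cross-trial matching fidelity, and the plateau drive-perturbation
probe.  They are the single source of the experiment configurations, shared
by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import matching, pipeline, preprocess, prolongation, sombrero
from .simulate import (PoolConfig, SpikeTrain, generate_command,
                       simulate_pool, synthesize_muaps_and_emg,
                       synthesize_torque)

#: pool for Delta-F recovery: 20 units on a 30% MVT triangular ramp; uniform
#: reporter gain 1.5 pps/%MVT and 2 %MVT hysteresis on the designated test
#: unit give a ground-truth Delta-F of 3.0 pps for every pair.
DELTA_F_TEST_UNIT = 12


def delta_f_recovery_config(seed: int, test_hysteresis: float = 2.0
                            ) -> PoolConfig:
    hyst = np.zeros(20)
    hyst[DELTA_F_TEST_UNIT] = test_hysteresis
    return PoolConfig(n_units=20, threshold_range=(2.0, 25.0),
                      threshold_shape=0.0, gain=1.5,
                      hysteresis=tuple(hyst), isi_cv=0.1, seed=seed)


def delta_f_recovery(seed: int, test_hysteresis: float = 2.0,
                     length_factor: float = 1.0):
    """Estimated vs true Delta-F of the designated test unit on one ramp."""
    cmd = generate_command("ramp", 0, 30, 3, 0)
    cfg = delta_f_recovery_config(seed, test_hysteresis)
    if length_factor != 1.0:
        from dataclasses import replace
        cfg = replace(cfg, length_factor=length_factor)
    trains, truth = simulate_pool(cfg, cmd)
    trace = synthesize_torque(trains, truth, noise_sd=0.0, seed=seed)
    uid = DELTA_F_TEST_UNIT
    sm = pipeline.smooth_pool([t for t in trains if t.unit_id <= uid])
    lm = prolongation.landmarks(trains[uid], trace, sm[uid])
    reporters = [(i, sm[i], float(trains[i].times[0]))
                 for i in range(uid) if i in sm]
    res = prolongation.delta_f(sm[uid], lm, reporters)
    return {"estimate": res.mean_delta_f,
            "truth": truth.true_delta_f(uid, 0),
            "n_pairs": len(res.surviving),
            "trains": trains, "truth_obj": truth, "trace": trace}


def classification_exactness(seed: int) -> bool:
    """Noiseless sombrero: do measured labels match the ground truth?"""
    cmd = generate_command("sombrero", 10, 30, 3, 10)
    cfg = PoolConfig(seed=seed, isi_cv=0.0, hysteresis=3.0,
                     length_factor=1.5)
    trains, truth = simulate_pool(cfg, cmd)
    windows = preprocess.segment_plateaus(cmd)
    cats = sombrero.classify_units(trains, windows)
    return all(c.category == (truth.categories[c.unit_id] or "none")
               for c in cats)


def sustained_durations(seed: int, hysteresis: float):
    """Measured sustained durations of ramp-recruited units (noiseless).

    Returns a list of (measured duration, threshold, effective hysteresis)
    for every cap/button unit, using the command-domain crossing.
    """
    cmd = generate_command("sombrero", 10, 30, 3, 10)
    cfg = PoolConfig(seed=seed, isi_cv=0.0, hysteresis=hysteresis,
                     length_factor=1.5)
    trains, truth = simulate_pool(cfg, cmd)
    windows = preprocess.segment_plateaus(cmd)
    cats = sombrero.classify_units(trains, windows)
    by_id = {t.unit_id: t for t in trains}
    out = []
    for c in cats:
        if c.category not in ("cap", "button"):
            continue
        s = sombrero.sustained_duration(by_id[c.unit_id],
                                        tq_rec=float(cmd.drive_at(c.t_rec)),
                                        cmd=cmd)
        out.append((s.sustained_dur, float(truth.thresholds[c.unit_id]),
                    float(truth.hysteresis_eff[c.unit_id])))
    return out


def sombrero_condition(seed: int, protocol: str = "sombrero",
                       length_factor: float = 1.0,
                       smooth_brims: bool = False) -> dict:
    """One sombrero/hold trial analysed end to end."""
    cmd = generate_command(protocol, 10, 30, 3, 10)
    cfg = PoolConfig(seed=seed, hysteresis=3.0, length_factor=length_factor)
    trains, truth = simulate_pool(cfg, cmd)
    trace = synthesize_torque(trains, truth, noise_sd=0.3, seed=seed)
    windows = preprocess.segment_plateaus(
        generate_command("sombrero", 10, 30, 3, 10))
    res = {"delta_cv": preprocess.delta_cv(trace, windows)}
    if protocol == "sombrero":
        full = pipeline.analyze_sombrero_trial(trains, trace, cmd,
                                               smooth_brims=smooth_brims)
        res.update(n_cap=full["n_cap"], n_button=full["n_button"],
                   n_brim=full["n_brim"],
                   prop_sustained=full["prop_sustained"],
                   brim_rate_delta=full["brim_rate_delta"])
    return res


def ramp_length_condition(seed: int, length_factor: float) -> dict:
    """Ramp-trial PIC metrics at one muscle length (ankle angle).

    Every unit carries hysteresis here (the whole pool has PICs); the
    length factor scales all of them.  Returns the designated test unit's
    Delta-F plus descending-duration and derecruitment-torque summaries over
    the recruited pool.
    """
    cmd = generate_command("ramp", 0, 30, 3, 0)
    cfg = PoolConfig(n_units=20, threshold_range=(2.0, 25.0),
                     threshold_shape=0.0, gain=1.5, hysteresis=2.0,
                     isi_cv=0.1, length_factor=length_factor, seed=seed)
    trains, truth = simulate_pool(cfg, cmd)
    trace = synthesize_torque(trains, truth, noise_sd=0.0, seed=seed)
    uid = DELTA_F_TEST_UNIT
    sm = pipeline.smooth_pool([t for t in trains if t.unit_id <= uid])
    lm = prolongation.landmarks(trains[uid], trace, sm[uid])
    reporters = [(i, sm[i], float(trains[i].times[0]))
                 for i in range(uid) if i in sm]
    res = prolongation.delta_f(sm[uid], lm, reporters)

    t_peak = float(trace.t[int(np.argmax(trace.torque_filt))])
    descend, tq_derec = [], []
    for tr in trains:
        if tr.n_spikes < 2:
            continue
        descend.append(float(tr.times[-1]) - t_peak)
        tq_derec.append(float(cmd.drive_at(tr.times[-1])))
    return {"delta_f": res.mean_delta_f,
            "descend_dur_mean": float(np.mean(descend)),
            "tq_derec_mean": float(np.mean(tq_derec))}


def matching_fidelity(seed: int, n_units: int = 15, n_trials: int = 3,
                      snr_db: float = 15.0, duration: float = 20.0) -> dict:
    """Cross-trial matching recall on synthetic EMG with known identities."""
    rng = np.random.default_rng(seed)
    templates_by_trial = {}
    centers = None
    for trial in range(n_trials):
        trains = []
        for u in range(n_units):
            t = np.sort(rng.uniform(0.1, duration - 0.1, 60))
            t = t[np.concatenate(([True], np.diff(t) > 0.02))]
            trains.append(SpikeTrain(unit_id=u, times=t,
                                     trial_id=f"trial{trial}"))
        tpls, emg = synthesize_muaps_and_emg(
            trains, duration, snr_db=snr_db, seed=seed * 101 + trial,
            unit_seed=seed)
        if centers is None:
            centers = [tpl.center for tpl in tpls]
        templates_by_trial[f"trial{trial}"] = {
            tr.unit_id: matching.spike_triggered_average(emg, tr)
            for tr in trains}
    pairs = matching.correlate_all(templates_by_trial)
    res = matching.assign_matches(pairs)

    true_pairs = [((f"trial{a}", u), (f"trial{b}", u))
                  for u in range(n_units)
                  for a in range(n_trials) for b in range(a + 1, n_trials)]
    recall = float(np.mean([res.mu_uid[x] == res.mu_uid[y]
                            for x, y in true_pairs]))
    far_merges = 0
    keys = sorted(res.mu_uid)
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1:]:
            if k1[1] != k2[1] and res.mu_uid[k1] == res.mu_uid[k2]:
                d = float(np.hypot(centers[k1[1]][0] - centers[k2[1]][0],
                                   centers[k1[1]][1] - centers[k2[1]][1]))
                if d >= 6.0:
                    far_merges += 1
    tpl0 = templates_by_trial["trial0"][0]
    return {"recall": recall, "far_false_merges": far_merges,
            "self_corr": matching.xcorr2_normalized(tpl0, tpl0),
            "n_pairs": len(true_pairs)}
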