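"""Brim/button/cap classification and sustained-discharge metrics.

On a sombrero trial (ramp superimposed on a stabilizing hold), units are
classified by where they were recruited and how far their discharge extends:
brim units recruit during plateau one, button units recruit and stop within
the centre ramp, and cap units recruit in the ramp but keep discharging into
the second plateau -- the signature of PIC-induced prolongation.  Sustained
discharge is measured against the "theoretical derecruitment" instant at
which torque falls back to the unit's recruitment torque on the descending
limb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PlateauWindows

#: an inter-spike gap of at least this many seconds breaks "maintained
#: discharge" (maintained discharge requires ISI < 1 s)
MAX_MAINTAINED_ISI = 1.0

SUSTAINED_THRESHOLD_S = 2.0


@dataclass
class MUCategory:
    unit_id: int
    category: str          # brim | button | cap | other | none
    t_rec: float
    discharge_end: float


@dataclass
class SustainedDischarge:
    unit_id: int
    t_theoretical_derec: float
    t_discharge_end: float
    sustained_dur: float   # signed
    no_crossing: bool = False


def discharge_end(train) -> float:
    """End of maintained discharge under the ISI < 1 s rule.

    Scanning the intervals in order, discharge terminates at the first spike
    followed by a gap of 1 s or more; with no such gap it ends at the last
    spike.
    """
    times = np.asarray(train.times, float)
    if times.size == 0:
        raise ValueError("empty spike train")
    isi = np.diff(times)
    breaks = np.flatnonzero(isi >= MAX_MAINTAINED_ISI)
    if breaks.size:
        return float(times[breaks[0]])
    return float(times[-1])


def classify_units(trains, windows: PlateauWindows) -> list:
    """Assign each unit a brim/button/cap/other category for one trial.

    Brim: recruited before the ramp window.  Ramp-recruited units are cap
    when their maintained discharge extends past the start of plateau two,
    button otherwise.  Units recruited during plateau two are "other"; units
    that never discharged are "none".
    """
    r0, r1 = windows.ramp
    p2_start = windows.plateau_two[0]
    out = []
    for tr in trains:
        if tr.times.size == 0:
            out.append(MUCategory(tr.unit_id, "none", np.nan, np.nan))
            continue
        t_rec = float(tr.times[0])
        end = discharge_end(tr)
        if t_rec < r0:
            cat = "brim"
        elif t_rec < r1:
            cat = "cap" if end > p2_start else "button"
        else:
            cat = "other"
        out.append(MUCategory(tr.unit_id, cat, t_rec, end))
    return out


def _descending_crossing(t, y, level, t_peak):
    """First time after ``t_peak`` where ``y`` falls to ``level``.

    Linear interpolation between samples; None when no crossing occurs
    before the record ends.
    """
    mask = t >= t_peak
    ts, ys = t[mask], y[mask]
    below = ys <= level
    if not np.any(below):
        return None
    k = int(np.argmax(below))
    if k == 0:
        return float(ts[0])
    t0, t1 = ts[k - 1], ts[k]
    y0, y1 = ys[k - 1], ys[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (y0 - level) / (y0 - y1) * (t1 - t0))


def theoretical_derecruitment(tq_rec: float, trace=None, cmd=None):
    """Descending-limb crossing of the recruitment torque.

    Prefers the noiseless command when given (simulated data); otherwise uses
    the 50 Hz-filtered torque with linear interpolation.  Returns
    (time, no_crossing_flag); when the signal never falls back to ``tq_rec``
    on the command either, the command end is NOT substituted -- the caller
    receives the flag and the command-domain crossing of whichever source
    does cross.
    """
    if cmd is not None:
        t = cmd.t
        y = cmd.drive
    elif trace is not None:
        t = trace.t
        y = trace.torque_pct
    else:
        raise ValueError("need a command or a torque trace")
    t_peak = float(t[int(np.argmax(y))])
    tc = _descending_crossing(np.asarray(t), np.asarray(y), tq_rec, t_peak)
    if tc is not None:
        return tc, False
    # no crossing on the measured signal: fall back to the command domain
    if trace is not None and cmd is not None:
        tc = _descending_crossing(cmd.t, cmd.drive, tq_rec,
                                  float(cmd.t[int(np.argmax(cmd.drive))]))
        if tc is not None:
            return tc, False
    return float(t[-1]), True


def sustained_duration(train, tq_rec: float, trace=None, cmd=None,
                       windows: PlateauWindows | None = None
                       ) -> SustainedDischarge:
    """Signed duration of discharge past theoretical derecruitment.

    ``tq_rec`` is the unit's recruitment torque (% MVT).  When a command is
    supplied its exact breakpoints define the descending crossing; the
    recruitment torque of simulated units should then also be read from the
    command domain for sample-exact comparisons.
    """
    if windows is not None and train.times.size:
        t_rec = float(train.times[0])
        if not (windows.ramp[0] <= t_rec < windows.ramp[1]):
            raise ValueError("unit was not recruited within the ramp window")
    t_theo, no_cross = theoretical_derecruitment(tq_rec, trace=trace, cmd=cmd)
    end = discharge_end(train)
    return SustainedDischarge(unit_id=train.unit_id,
                              t_theoretical_derec=t_theo,
                              t_discharge_end=end,
                              sustained_dur=end - t_theo,
                              no_crossing=no_cross)


def proportion_sustained(categories, sustained,
                         threshold_s: float = SUSTAINED_THRESHOLD_S,
                         denominator: str = "ramp") -> float | None:
    """Fraction of ramp-recruited units with long sustained discharge.

    Numerator: cap units sustaining discharge > ``threshold_s`` seconds.
    Denominator "ramp" counts units recruited in the ramp window (cap +
    button); "cap+brim" is the alternative grouping.  None (flagged) when
    the denominator is empty.
    """
    sus = {s.unit_id: s.sustained_dur for s in sustained}
    caps = [c for c in categories if c.category == "cap"]
    n_qual = sum(1 for c in caps if sus.get(c.unit_id, -np.inf) > threshold_s)
    if denominator == "ramp":
        denom = sum(1 for c in categories if c.category in ("cap", "button"))
    elif denominator == "cap+brim":
        denom = sum(1 for c in categories if c.category in ("cap", "brim"))
    else:
        raise ValueError("denominator must be 'ramp' or 'cap+brim'")
    if denom == 0:
        return None
    return n_qual / denom


def plateau_rate_delta(smoothed_by_unit, windows: PlateauWindows,
                       fs_eval: float = 256.0) -> dict:
    """Per-unit mean smoothed rate in plateau two minus plateau one.

    ``smoothed_by_unit`` maps unit_id -> SmoothedRate.  Units whose smoothed
    support does not overlap a plateau are excluded with a reason.  The mean
    is taken over the overlap of the plateau window and the unit's active
    span, evaluated at ``fs_eval`` (the curve is smooth at the ~1 s scale, so
    dense 2048 Hz evaluation is unnecessary).
    """
    deltas, excluded = {}, {}
    for uid, sm in smoothed_by_unit.items():
        means = []
        for win in (windows.plateau_one, windows.plateau_two):
            lo = max(win[0], sm.support[0])
            hi = min(win[1], sm.support[1])
            if hi <= lo:
                means.append(None)
                continue
            grid = np.linspace(lo, hi, max(int((hi - lo) * fs_eval), 2))
            means.append(float(np.nanmean(sm.at(grid))))
        if means[0] is None or means[1] is None:
            which = "one" if means[0] is None else "two"
            excluded[uid] = f"inactive_in_plateau_{which}"
            continue
        deltas[uid] = means[1] - means[0]
    return {"delta_pps": deltas, "excluded": excluded}
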