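"""Ramp-contraction metrics: landmarks, Delta-F, and descending-phase measures.

Delta-F quantifies PIC magnitude from a pair of motor units: the drop in a
lower-threshold reporter unit's smoothed discharge rate between a higher
threshold test unit's recruitment and derecruitment.  A positive value
indicates onset-offset hysteresis.  Pairs are screened with the standard
exclusion criteria (rate-rate r^2 > 0.7 for common drive, recruitment-time
separation >= 1 s for full PIC activation in the reporter, and reporter rate
range >= 0.5 pps against saturation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

#: exclusion thresholds for test/reporter pairs
R2_MIN = 0.7           # keep pairs with r^2 strictly greater
REC_DIFF_MIN = 1.0     # s
REPORTER_RANGE_MIN = 0.5  # pps


@dataclass
class MULandmarks:
    """Recruitment/derecruitment times, torques and landmark rates."""

    t_rec: float
    t_derec: float
    tq_rec: float
    tq_derec: float
    rate_rec: float = np.nan
    rate_peak: float = np.nan
    rate_derec: float = np.nan

    def __post_init__(self):
        if self.t_derec < self.t_rec:
            raise ValueError("derecruitment precedes recruitment")


@dataclass
class PairResult:
    reporter_id: int
    delta_f: float
    r2: float
    rec_time_diff: float
    reporter_range: float
    excluded_reason: str | None = None


@dataclass
class DeltaFResult:
    test_id: int
    pairs: list = field(default_factory=list)

    @property
    def surviving(self):
        return [p for p in self.pairs if p.excluded_reason is None]

    @property
    def mean_delta_f(self):
        """Mean over non-excluded pairs; None when no pair survives."""
        ok = self.surviving
        if not ok:
            return None
        return float(np.mean([p.delta_f for p in ok]))


@dataclass
class RampMetrics:
    ascend_dur: float
    descend_dur: float
    adr: float
    tq_derec: float
    landmarks: MULandmarks


def landmarks(train, trace, smoothed=None) -> MULandmarks:
    """Per-unit landmarks from the first/last spike and the torque trace."""
    if train.times.size == 0:
        raise ValueError("empty spike train has no landmarks")
    t_rec = float(train.times[0])
    t_derec = float(train.times[-1])
    if t_rec < trace.t[0] - 1e-9 or t_derec > trace.t[-1] + 1e-9:
        raise ValueError("torque trace does not cover the spike span")
    lm = MULandmarks(t_rec=t_rec, t_derec=t_derec,
                     tq_rec=trace.pct_at(t_rec),
                     tq_derec=trace.pct_at(t_derec))
    if smoothed is not None:
        lm.rate_rec = float(smoothed.at(t_rec))
        lm.rate_derec = float(smoothed.at(t_derec))
        lm.rate_peak = float(np.nanmax(smoothed.rate))
    return lm


def rate_rate_r2(test, reporter, fs: float = 2048.0):
    """Squared Pearson correlation of two smoothed curves.

    Both curves are resampled to a common uniform grid over the test unit's
    active span (intersected with the reporter's support).  Returns None when
    either curve has zero variance there.
    """
    lo = max(test.support[0], reporter.support[0])
    hi = min(test.support[1], reporter.support[1])
    if hi <= lo:
        return None
    n = max(int(round((hi - lo) * fs)), 2)
    grid = np.linspace(lo, hi, n)
    a, b = test.sample(grid), reporter.sample(grid)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(pearsonr(a, b)[0] ** 2)


def delta_f(test_smoothed, test_landmarks: MULandmarks, reporters,
            fs: float = 2048.0) -> DeltaFResult:
    """Delta-F of one test unit against candidate reporter units.

    ``reporters`` is a list of (reporter_id, SmoothedRate, reporter_t_rec).
    Eligible reporters were recruited before the test unit and their smoothed
    support covers both test landmarks; ineligible candidates are silently
    skipped.  For each eligible pair the reporter rate is read at the test
    unit's recruitment and derecruitment, and the exclusion criteria are
    applied in the order r^2, recruitment separation, reporter range (the
    first violated criterion is recorded).
    """
    t_rec, t_derec = test_landmarks.t_rec, test_landmarks.t_derec
    result = DeltaFResult(test_id=getattr(test_smoothed, "unit_id", -1))
    for rep_id, rep_sm, rep_t_rec in reporters:
        if rep_t_rec >= t_rec or not rep_sm.covers(t_rec, t_derec):
            continue
        df = float(rep_sm.at(t_rec) - rep_sm.at(t_derec))
        r2 = rate_rate_r2(test_smoothed, rep_sm, fs=fs)
        rec_diff = t_rec - rep_t_rec
        lo = max(t_rec, rep_sm.support[0])
        hi = min(t_derec, rep_sm.support[1])
        n = max(int(round((hi - lo) * fs)), 2)
        seg = rep_sm.sample(np.linspace(lo, hi, n))
        rng = float(np.nanmax(seg) - np.nanmin(seg))
        reason = None
        if r2 is None:
            reason = "r2_undefined"
        elif r2 <= R2_MIN:
            reason = "r2_below_threshold"
        elif rec_diff < REC_DIFF_MIN:
            reason = "recruitment_too_close"
        elif rng < REPORTER_RANGE_MIN:
            reason = "reporter_range_too_small"
        result.pairs.append(PairResult(
            reporter_id=rep_id, delta_f=df,
            r2=np.nan if r2 is None else r2,
            rec_time_diff=rec_diff, reporter_range=rng,
            excluded_reason=reason))
    return result


def descending_metrics(lm: MULandmarks, trace) -> RampMetrics:
    """Signed ascending/descending discharge durations about peak torque.

    Peak torque is taken from the filtered trace (earliest sample on ties).
    descend_dur = t_derec - t_peak may be negative when a unit derecruits
    before the peak; the ascending-descending ratio ADR normalizes the
    imbalance by the total discharge duration.
    """
    t_peak = float(trace.t[int(np.argmax(trace.torque_filt))])
    ascend = t_peak - lm.t_rec
    descend = lm.t_derec - t_peak
    total = lm.t_derec - lm.t_rec
    adr = (ascend - descend) / total if total > 0 else np.nan
    return RampMetrics(ascend_dur=ascend, descend_dur=descend, adr=adr,
                       tq_derec=lm.tq_derec, landmarks=lm)
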