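"""Torque conditioning, plateau segmentation and variability metrics.

Raw ankle torque is digitized at 2048 Hz; analysis uses a fifth-order 50 Hz
Butterworth low-pass (zero-phase by default, so landmark torques are not
lag-shifted), while the 125 ms moving average mirrors the smoothing applied
to the visual-feedback signal.  Force steadiness is summarized as the
coefficient of variation (CV) of % MVT torque within a plateau window, and
the sombrero/hold comparison uses the plateau-two minus plateau-one change
in CV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt


@dataclass
class TorqueTrace:
    """Sampled torque with raw/filtered Nm and % MVT representations."""

    t: np.ndarray
    torque_raw: np.ndarray
    torque_filt: np.ndarray
    torque_pct: np.ndarray
    mvt: float
    fs: float

    def __post_init__(self):
        n = self.t.size
        if not (self.torque_raw.size == self.torque_filt.size
                == self.torque_pct.size == n):
            raise ValueError("torque vectors must share one length")
        if self.mvt <= 0 or self.fs <= 0:
            raise ValueError("mvt and fs must be positive")

    @classmethod
    def from_raw(cls, t, raw_nm, mvt: float, fs: float = 2048.0,
                 zero_phase: bool = True) -> "TorqueTrace":
        t = np.asarray(t, float)
        raw_nm = np.asarray(raw_nm, float)
        filt = filter_torque(raw_nm, fs, zero_phase=zero_phase)
        return cls(t=t, torque_raw=raw_nm, torque_filt=filt,
                   torque_pct=100.0 * filt / mvt, mvt=mvt, fs=fs)

    def pct_at(self, time: float) -> float:
        """% MVT torque at the sample nearest ``time``."""
        i = int(np.clip(round((time - self.t[0]) * self.fs), 0,
                        self.t.size - 1))
        return float(self.torque_pct[i])


@dataclass(frozen=True)
class PlateauWindows:
    """Analysis windows (s) for a sombrero or matched hold trial."""

    plateau_one: tuple
    plateau_two: tuple
    ramp: tuple

    def __post_init__(self):
        if not (self.plateau_one[1] <= self.ramp[0]
                and self.ramp[1] <= self.plateau_two[0]):
            raise ValueError("windows must be ordered and non-overlapping")


def filter_torque(raw, fs: float, cutoff: float = 50.0,
                  order: int = 5, zero_phase: bool = True) -> np.ndarray:
    """Fifth-order Butterworth low-pass at 50 Hz.

    ``zero_phase`` applies the filter forward and backward (squared magnitude
    response, no lag); the single-pass variant keeps the textbook -3 dB point
    at the cutoff.
    """
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} must exceed twice the {cutoff} Hz cutoff")
    raw = np.asarray(raw, float)
    sos = butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, raw) if zero_phase else sosfilt(sos, raw)


def feedback_smooth(raw, fs: float, window_s: float = 0.125) -> np.ndarray:
    """Centered 125 ms moving average with truncated edge windows."""
    n = int(round(window_s * fs))
    if n < 2:
        raise ValueError("window must span at least 2 samples")
    raw = np.asarray(raw, float)
    kernel = np.ones(n)
    num = np.convolve(raw, kernel, mode="same")
    den = np.convolve(np.ones_like(raw), kernel, mode="same")
    return num / den


def segment_plateaus(cmd) -> PlateauWindows:
    """Copy plateau/ramp windows from the command's analytic breakpoints.

    Windows are never inferred from the torque signal; holds inherit the
    windows of the matched sombrero because both protocols record the same
    segment labels.
    """
    seg = cmd.segments
    missing = {"plateau_one", "plateau_two", "ramp"} - set(seg)
    if missing:
        raise ValueError(
            f"command lacks plateau segmentation (missing {sorted(missing)}); "
            "only sombrero/hold protocols have plateaus")
    return PlateauWindows(plateau_one=tuple(seg["plateau_one"]),
                          plateau_two=tuple(seg["plateau_two"]),
                          ramp=tuple(seg["ramp"]))


def _window_slice(trace: TorqueTrace, window, trim: float):
    lo, hi = window[0] + trim, window[1] - trim
    if hi <= lo:
        raise ValueError("window collapses after trimming")
    mask = (trace.t >= lo) & (trace.t <= hi)
    if not np.any(mask):
        raise ValueError("window outside trace span")
    return trace.torque_pct[mask]


def torque_cv(trace: TorqueTrace, window, trim: float = 0.0) -> float:
    """CV (%) = 100 * sample SD / mean of % MVT torque within ``window``.

    ``trim`` (s) shrinks the window symmetrically to avoid ramp-transition
    transients.  A non-positive mean signals a failed trial and is rejected.
    """
    x = _window_slice(trace, window, trim)
    m = float(np.mean(x))
    if m <= 0:
        raise ValueError("non-positive mean torque in window (failed trial?)")
    return 100.0 * float(np.std(x, ddof=1)) / m


def delta_cv(trace: TorqueTrace, windows: PlateauWindows,
             trim: float = 0.5) -> float:
    """Change in torque CV between plateaus: CV(plateau two) - CV(plateau one)."""
    return (torque_cv(trace, windows.plateau_two, trim=trim)
            - torque_cv(trace, windows.plateau_one, trim=trim))


def flag_failed_trial(trace: TorqueTrace, cmd, tolerance: float = 5.0,
                      max_fraction: float = 0.5) -> dict:
    """Screen a trial for gross deviation from the commanded torque.

    A segment is flagged when |torque_pct - command| exceeds ``tolerance``
    % MVT for more than ``max_fraction`` of its samples.  Trials are flagged,
    never auto-dropped.
    """
    report = {}
    for label, (lo, hi) in cmd.segments.items():
        mask = (trace.t >= lo) & (trace.t <= hi)
        if not np.any(mask):
            continue
        dev = np.abs(trace.torque_pct[mask] - cmd.drive_at(trace.t[mask]))
        frac = float(np.mean(dev > tolerance))
        report[label] = frac
    flagged = any(f > max_fraction for f in report.values())
    if flagged:
        warnings.warn("trial deviates from the commanded torque", stacklevel=2)
    return {"flagged": flagged, "fraction_out": report}
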