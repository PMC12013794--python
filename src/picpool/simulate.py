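"""Synthetic motoneuron pool with programmable PIC hysteresis.

This module generates everything the analysis side of the package consumes:
command trajectories (sombrero / hold / ramp), motor-unit spike trains from a
recruited pool whose units carry an onset--offset hysteresis standing in for
dendritic persistent inward currents (PICs), twitch-summed torque, and
spatio-temporal MUAP templates on a 13x5 electrode grid with surface-EMG
mixtures.

The PIC model is deliberately minimal: unit *i* is recruited when the common
drive (in % MVT-equivalent units) first reaches its threshold theta_i; once
recruited, a constant offset Delta_i * length_factor is added to its effective
drive, so it is derecruited only when the drive falls below
theta_i - Delta_i * length_factor.  This drive-domain hysteresis is the
smallest mechanism that produces the discharge signatures the analysis
measures (Delta-F, prolonged descending discharge, cap units) while keeping
every ground-truth landmark analytically available for parameter-recovery
tests.  While active, a unit's mean rate is
``rate_min + gain_i * (drive + Delta_i*lf - theta_i)`` and spikes are drawn
from a gamma-renewal process via time rescaling.  A spike is emitted exactly
at the recruitment and derecruitment crossings, so measured landmarks coincide
with true event times in the noiseless limit.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .preprocess import TorqueTrace

logger = logging.getLogger(__name__)

FS_DEFAULT = 2048.0

#: length_factor presets for ankle-angle conditions (short agonist muscle =
#: higher spinal excitability = larger effective hysteresis).
LENGTH_FACTORS = {"long": 0.7, "mid": 1.0, "short": 1.5}


# ---------------------------------------------------------------------------
# command trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommandProfile:
    """Piecewise-linear drive trajectory on a uniform 2048 Hz grid.

    ``breakpoints`` holds the analytic (time, drive) knots; ``segments`` maps
    labels (plateau_one, ramp_up, ramp_down, ramp, plateau_two, hold) to
    (start, end) windows in seconds, recorded exactly at the breakpoints.
    """

    t: np.ndarray
    drive: np.ndarray
    segments: dict
    breakpoints: tuple  # ((t0, v0), (t1, v1), ...)
    protocol: str
    fs: float = FS_DEFAULT

    @property
    def t_end(self) -> float:
        return self.breakpoints[-1][0]

    def drive_at(self, times):
        bt = np.array([b[0] for b in self.breakpoints])
        bv = np.array([b[1] for b in self.breakpoints])
        return np.interp(times, bt, bv)


def _grid(t_end: float, fs: float) -> np.ndarray:
    n = int(math.floor(t_end * fs)) + 1
    return np.arange(n) / fs


def generate_command(protocol: str, mvt_plateau: float = 10.0,
                     mvt_peak: float = 30.0, ramp_rate: float = 3.0,
                     plateau_dur: float = 10.0,
                     fs: float = FS_DEFAULT) -> CommandProfile:
    """Build a sombrero, hold, or triangular-ramp command trajectory.

    The sombrero is a triangular ramp (``mvt_plateau`` -> ``mvt_peak`` ->
    ``mvt_plateau`` at ``ramp_rate`` % MVT/s) superimposed on a sustained
    stabilizing plateau of ``plateau_dur`` seconds on either side.  A hold is
    a constant plateau of the same total duration with plateau windows
    matching the corresponding sombrero.  A ramp is a 0 -> peak -> 0 triangle
    (``plateau_dur`` ignored).
    """
    if protocol not in ("sombrero", "hold", "ramp"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if ramp_rate <= 0:
        raise ValueError("ramp_rate must be positive")
    if not mvt_peak >= mvt_plateau >= 0:
        raise ValueError("require mvt_peak >= mvt_plateau >= 0")

    if protocol == "ramp":
        t_up = mvt_peak / ramp_rate
        bps = ((0.0, 0.0), (t_up, mvt_peak), (2 * t_up, 0.0))
        segments = {"ramp_up": (0.0, t_up), "ramp_down": (t_up, 2 * t_up),
                    "ramp": (0.0, 2 * t_up)}
    else:
        if plateau_dur <= 0:
            raise ValueError("plateau_dur must be positive")
        half = (mvt_peak - mvt_plateau) / ramp_rate
        t1 = plateau_dur
        t2 = t1 + half
        t3 = t2 + half
        t4 = t3 + plateau_dur
        segments = {"plateau_one": (0.0, t1), "ramp_up": (t1, t2),
                    "ramp_down": (t2, t3), "ramp": (t1, t3),
                    "plateau_two": (t3, t4)}
        if protocol == "sombrero":
            bps = ((0.0, mvt_plateau), (t1, mvt_plateau), (t2, mvt_peak),
                   (t3, mvt_plateau), (t4, mvt_plateau))
        else:  # hold: constant drive, windows matched to the sombrero
            bps = ((0.0, mvt_plateau), (t4, mvt_plateau))
            segments = dict(segments, hold=(0.0, t4))

    t = _grid(bps[-1][0], fs)
    bt = np.array([b[0] for b in bps])
    bv = np.array([b[1] for b in bps])
    drive = np.interp(t, bt, bv)
    return CommandProfile(t=t, drive=drive, segments=segments,
                          breakpoints=bps, protocol=protocol, fs=fs)


def _knots(cmd):
    bt = np.fromiter((b[0] for b in cmd.breakpoints), float)
    bv = np.fromiter((b[1] for b in cmd.breakpoints), float)
    return bt, bv


def recruitment_time(cmd: CommandProfile, threshold: float):
    """First time the drive reaches ``threshold``, exact on the knots.

    Returns None when the drive never reaches the threshold.
    """
    bt, bv = _knots(cmd)
    if bv[0] >= threshold:
        return float(bt[0])
    hit = np.flatnonzero(bv >= threshold)
    if hit.size == 0:
        return None
    k = int(hit[0])  # first knot at/above: the crossing lies in (k-1, k]
    va, vb = bv[k - 1], bv[k]
    return float(bt[k - 1] + (threshold - va) / (vb - va)
                 * (bt[k] - bt[k - 1]))


def derecruitment_time(cmd: CommandProfile, threshold: float,
                       hysteresis: float, t_rec: float):
    """First time after ``t_rec`` the drive falls below theta - Delta.

    Falls back to the command end when the derecruitment condition is never
    met (the unit discharges through the end of the trial).
    """
    level = threshold - hysteresis
    bt, bv = _knots(cmd)
    hit = np.flatnonzero((bt > t_rec) & (bv < level))
    if hit.size == 0:
        return cmd.t_end
    k = int(hit[0])
    ta = max(float(bt[k - 1]), t_rec)
    va = float(np.interp(ta, bt, bv))
    if va <= level:
        return ta
    vb = float(bv[k])
    return ta + (va - level) / (va - vb) * (float(bt[k]) - ta)


# ---------------------------------------------------------------------------
# pool configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolConfig:
    """Parameters of the simulated motoneuron pool.

    thresholds span ``threshold_range`` (% MVT) with an exponential skew
    toward low values controlled by ``threshold_shape`` (0 = evenly spaced).
    ``hysteresis`` is the PIC offset Delta_i in % MVT-equivalent drive; it is
    scaled by ``length_factor`` (short muscle > 1, long < 1) before use.
    ``gain`` maps excess drive to discharge rate (pps per % MVT); ``isi_cv``
    is the coefficient of variation of the gamma-renewal inter-spike
    intervals (0 = deterministic).
    """

    n_units: int = 20
    threshold_range: tuple = (1.0, 25.0)
    threshold_shape: float = 3.0
    custom_thresholds: tuple | None = None  # explicit theta_i, overrides range
    rate_min: float = 5.0
    gain: float | np.ndarray = 1.0
    hysteresis: float | np.ndarray = 2.0
    isi_cv: float = 0.1
    length_factor: float = 1.0
    seed: int = 0
    twitch_peak_ratio: float = 30.0   # largest/smallest twitch amplitude
    twitch_tc_range: tuple = (0.090, 0.030)  # s, low- to high-threshold
    pic_onset_tau: float = 0.0        # optional first-order PIC onset (s)
    feedback_gain: float = 0.0        # optional drive renormalization

    def __post_init__(self):
        lo, hi = self.threshold_range
        if not (0 <= lo < hi):
            raise ValueError("threshold_range must satisfy 0 <= min < max")
        if not 0 <= self.isi_cv <= 0.5:
            raise ValueError("isi_cv must lie in [0, 0.5]")
        if self.length_factor <= 0:
            raise ValueError("length_factor must be positive")
        if np.any(np.asarray(self.hysteresis) < 0):
            raise ValueError("hysteresis must be non-negative")
        if self.custom_thresholds is not None:
            th = np.asarray(self.custom_thresholds, float)
            if th.size != self.n_units:
                raise ValueError("custom_thresholds must have n_units entries")
            if th.size > 1 and np.any(np.diff(th) < 0):
                raise ValueError("thresholds must be sorted ascending")

    def thresholds(self) -> np.ndarray:
        if self.custom_thresholds is not None:
            return np.asarray(self.custom_thresholds, float)
        lo, hi = self.threshold_range
        n = self.n_units
        x = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        a = self.threshold_shape
        if abs(a) < 1e-9:
            w = x
        else:
            w = (np.exp(a * x) - 1.0) / (np.exp(a) - 1.0)
        return lo + (hi - lo) * w

    def gains(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.gain, float),
                               (self.n_units,)).copy()

    def hysteresis_arr(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.hysteresis, float),
                               (self.n_units,)).copy()

    def config_hash(self) -> str:
        rep = repr(self).encode()
        return hashlib.sha1(rep).hexdigest()[:10]


@dataclass
class SpikeTrain:
    """Discharge times (s, strictly increasing) of one unit in one trial."""

    unit_id: int
    times: np.ndarray
    trial_id: str = "trial"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class PoolGroundTruth:
    """Simulator-side truth for every downstream metric.

    Per-unit arrays are aligned with unit ids 0..n-1; units never recruited
    carry NaN event times and category None.
    """

    thresholds: np.ndarray
    hysteresis_eff: np.ndarray     # Delta_i * length_factor, % MVT
    gains: np.ndarray
    rate_min: float
    t_rec: np.ndarray
    t_derec: np.ndarray
    twitch_peak: np.ndarray
    twitch_tc: np.ndarray
    categories: list
    cmd: CommandProfile

    def true_delta_f(self, test: int, reporter: int) -> float:
        """Ground-truth Delta-F (pps) of a test/reporter pair.

        The reporter's rate tracks the drive with slope gain_r, and the test
        unit's hysteresis moves its derecruitment drive down by Delta_t*lf,
        so the reporter's rate drop between the test landmarks is exactly
        gain_r * Delta_t * lf.
        """
        return float(self.gains[reporter] * self.hysteresis_eff[test])

    def rate_at(self, unit: int, times):
        """True instantaneous rate of ``unit`` at ``times`` (NaN if inactive)."""
        times = np.asarray(times, float)
        d = self.cmd.drive_at(times)
        r = (self.rate_min + self.gains[unit]
             * (d + self.hysteresis_eff[unit] - self.thresholds[unit]))
        active = (times >= self.t_rec[unit]) & (times <= self.t_derec[unit])
        return np.where(active, r, np.nan)

    def recruited(self) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.t_rec))


def _categorize(t_rec, t_end_discharge, segments):
    """brim / button / cap / other classification from event times."""
    if "ramp" not in segments:
        return None
    r0, r1 = segments["ramp"]
    if np.isnan(t_rec):
        return None
    if t_rec < r0:
        return "brim"
    if t_rec < r1:
        p2 = segments.get("plateau_two", (r1, r1))[0]
        return "cap" if t_end_discharge > p2 else "button"
    return "other"


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

def _unit_rate_fn(cmd, theta, delta_eff, gain, rate_min):
    def rate(times):
        return rate_min + gain * (cmd.drive_at(times) + delta_eff - theta)
    return rate


def _draw_spikes(cmd, t_rec, t_derec, rate_fn, isi_cv, rng):
    """Spike times on [t_rec, t_derec] by time-rescaled gamma renewal.

    The cumulative intensity Lambda(t) is integrated on the command grid
    (exact for a piecewise-linear rate except in the sample straddling a
    breakpoint); unit-mean gamma increments are inverted through Lambda.
    Spikes are pinned to both threshold crossings: the first spike sits at
    t_rec, and the final event at t_derec (the last interior spike is snapped
    there when it would land within half a mean ISI of the boundary).
    """
    if t_derec <= t_rec:
        return np.array([t_rec])
    fs = cmd.fs
    inner = cmd.t[(cmd.t > t_rec) & (cmd.t < t_derec)]
    tloc = np.concatenate(([t_rec], inner, [t_derec]))
    r = np.maximum(rate_fn(tloc), 1e-9)
    lam = np.concatenate(([0.0], np.cumsum(np.diff(tloc) * (r[:-1] + r[1:]) / 2)))
    total = lam[-1]
    if total <= 0:
        return np.array([t_rec, t_derec])

    if isi_cv <= 0:
        marks = np.arange(1.0, total + 1e-12)
    else:
        shape = 1.0 / isi_cv ** 2
        # draw enough increments to cover the total rescaled mass
        n_guess = int(total * 1.5) + 20
        incs = rng.gamma(shape, scale=1.0 / shape, size=n_guess)
        while incs.sum() < total:
            incs = np.concatenate(
                [incs, rng.gamma(shape, scale=1.0 / shape, size=n_guess)])
        marks = np.cumsum(incs)
        marks = marks[marks < total]
    interior = np.interp(marks, lam, tloc)

    times = np.concatenate(([t_rec], interior))
    # snap-or-append the derecruitment event spike
    end_isi = 1.0 / max(rate_fn(np.array([t_derec]))[0], 1e-9)
    if times[-1] > t_derec - 0.5 * end_isi and times.size > 1:
        times[-1] = t_derec
    else:
        times = np.append(times, t_derec)
    # guard against duplicate samples after snapping
    keep = np.concatenate(([True], np.diff(times) > 0.25 / fs))
    return times[keep]


def _feedback_drive(cmd, cfg, thresholds, deltas, gains, twitch_peak,
                    twitch_tc, mvt_au):
    """Proportional drive renormalization toward the command torque.

    Integrates a per-sample controller: the effective common drive is nudged
    so the pool's predicted steady-state torque (sum of active units'
    rate * twitch impulse) tracks the commanded % MVT.  Units recruit and
    derecruit against this effective drive, so cap units discharging in
    plateau two push the drive below the command and lower brim rates.
    """
    t = cmd.t
    target = cmd.drive
    n = cfg.n_units
    imp = twitch_peak * twitch_tc * math.e  # twitch impulse per spike
    e = np.empty_like(t)
    e[0] = target[0]
    active = cmd.drive_at(np.array([t[0]]))[0] >= thresholds
    kp = cfg.feedback_gain
    dt = 1.0 / cmd.fs
    drive_hist = np.empty_like(t)
    for k in range(t.size):
        ek = e[k]
        active = np.where(active, ek >= thresholds - deltas, ek >= thresholds)
        rates = np.where(
            active, cfg.rate_min + gains * (ek + deltas - thresholds), 0.0)
        tq = 100.0 * np.sum(rates * imp) / mvt_au
        drive_hist[k] = ek
        if k + 1 < t.size:
            e[k + 1] = ek + kp * (target[k + 1] - tq) * dt
    return drive_hist


def simulate_pool(cfg: PoolConfig, cmd: CommandProfile,
                  trial_id: str = "trial"):
    """Simulate the pool's discharge on a command trajectory.

    Returns (spike trains, PoolGroundTruth).  Units whose threshold exceeds
    the peak drive are returned with empty trains.  Identical (cfg, cmd)
    yield identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    theta = cfg.thresholds()
    gains = cfg.gains()
    deltas = cfg.hysteresis_arr() * cfg.length_factor
    n = cfg.n_units

    # size-principle twitches: amplitude grows, contraction time shrinks
    x = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    twitch_peak = np.exp(np.log(cfg.twitch_peak_ratio) * x)
    tc0, tc1 = cfg.twitch_tc_range
    twitch_tc = tc0 + (tc1 - tc0) * x

    eff_cmd = cmd
    if cfg.feedback_gain > 0:
        mvt_au = float(np.sum(
            (cfg.rate_min + gains * (100.0 + deltas - theta))
            * twitch_peak * twitch_tc * math.e))
        drive = _feedback_drive(cmd, cfg, theta, deltas, gains,
                                twitch_peak, twitch_tc, mvt_au)
        # re-knot on a decimated grid: the effective drive is no longer
        # piecewise linear between the analytic breakpoints
        stride = max(1, cmd.t.size // 4096)
        kt = np.append(cmd.t[::stride], cmd.t[-1])
        kv = np.append(drive[::stride], drive[-1])
        eff_cmd = replace(cmd, drive=drive,
                          breakpoints=tuple(zip(kt.tolist(), kv.tolist())))

    trains, t_rec, t_derec, cats = [], np.full(n, np.nan), np.full(n, np.nan), []
    for i in range(n):
        unit_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0])
        tr = recruitment_time(eff_cmd, theta[i])
        if tr is None:
            trains.append(SpikeTrain(unit_id=i, times=np.array([]),
                                     trial_id=trial_id))
            cats.append(None)
            continue
        td = derecruitment_time(eff_cmd, theta[i], deltas[i], tr)
        rate_fn = _unit_rate_fn(eff_cmd, theta[i], deltas[i], gains[i],
                                cfg.rate_min)
        times = _draw_spikes(eff_cmd, tr, td, rate_fn, cfg.isi_cv, unit_rng)
        trains.append(SpikeTrain(unit_id=i, times=times, trial_id=trial_id))
        t_rec[i], t_derec[i] = tr, td
        cats.append(_categorize(tr, td, cmd.segments))

    truth = PoolGroundTruth(thresholds=theta, hysteresis_eff=deltas,
                            gains=gains, rate_min=cfg.rate_min,
                            t_rec=t_rec, t_derec=t_derec,
                            twitch_peak=twitch_peak, twitch_tc=twitch_tc,
                            categories=cats, cmd=cmd)
    logger.info("simulate_pool seed=%d hash=%s units=%d recruited=%d",
                cfg.seed, cfg.config_hash(), n, truth.recruited().size)
    return trains, truth


# ---------------------------------------------------------------------------
# torque synthesis
# ---------------------------------------------------------------------------

def twitch_kernel(peak: float, tc: float, fs: float = FS_DEFAULT) -> np.ndarray:
    """Sampled twitch P*(t/Tc)*exp(1 - t/Tc), truncated at 7*Tc."""
    t = np.arange(0.0, 7.0 * tc, 1.0 / fs)
    return peak * (t / tc) * np.exp(1.0 - t / tc)


def mvt_constant(truth: PoolGroundTruth) -> float:
    """Arbitrary-unit MVT: noiseless steady torque at a 100% drive command.

    Under a sustained drive every unit fires at its 100%-drive rate and the
    mean twitch-summed torque is rate * integral(twitch) = r * P * Tc * e.
    """
    r100 = (truth.rate_min + truth.gains
            * (100.0 + truth.hysteresis_eff - truth.thresholds))
    return float(np.sum(r100 * truth.twitch_peak * truth.twitch_tc * math.e))


def synthesize_torque(trains, truth: PoolGroundTruth, noise_sd: float = 0.3,
                      fs: float = FS_DEFAULT, mvt_nm: float = 40.0,
                      rescale: bool = True, seed: int | None = None
                      ) -> TorqueTrace:
    """Twitch-summed torque with band-limited noise, in Nm and % MVT.

    Each spike contributes one twitch; torque in arbitrary units is converted
    to % MVT by the pool's calibration constant and (by default) rescaled by
    a single least-squares gain onto the command so plateau torque sits near
    the commanded level.  Noise is white Gaussian low-passed at 10 Hz with
    standard deviation ``noise_sd`` % MVT.
    """
    from scipy.signal import butter, sosfiltfilt

    cmd = truth.cmd
    t = cmd.t
    torque_au = np.zeros_like(t)
    for tr in trains:
        if tr.n_spikes == 0:
            continue
        k = twitch_kernel(truth.twitch_peak[tr.unit_id],
                          truth.twitch_tc[tr.unit_id], fs)
        idx = np.clip(np.round(tr.times * fs).astype(int), 0, t.size - 1)
        delta = np.zeros_like(t)
        np.add.at(delta, idx, 1.0)
        torque_au += np.convolve(delta, k)[: t.size]

    pct = 100.0 * torque_au / mvt_constant(truth)
    if rescale and np.any(pct > 0):
        denom = float(np.dot(pct, pct))
        if denom > 0:
            pct = pct * (float(np.dot(pct, cmd.drive)) / denom)

    if noise_sd > 0:
        rng = np.random.default_rng(0 if seed is None else seed)
        white = rng.standard_normal(t.size)
        sos = butter(4, 10.0, btype="low", fs=fs, output="sos")
        noise = sosfiltfilt(sos, white)
        noise *= noise_sd / max(np.std(noise), 1e-12)
        pct = pct + noise

    raw_nm = pct / 100.0 * mvt_nm
    return TorqueTrace.from_raw(t, raw_nm, mvt=mvt_nm, fs=fs)


# ---------------------------------------------------------------------------
# MUAP templates and surface EMG
# ---------------------------------------------------------------------------

GRID_SHAPE = (13, 5)


@dataclass
class MUAPTemplate:
    """Per-channel action-potential window on the electrode grid.

    ``waveform`` has shape (rows*cols, n_samples); ``mask`` marks channels
    present; ``center`` is the (row, col) of the spatial peak.
    """

    waveform: np.ndarray
    center: tuple
    grid_shape: tuple = GRID_SHAPE
    mask: np.ndarray | None = None
    fs: float = FS_DEFAULT
    n_spikes: int = 0
    low_confidence: bool = False

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.ones(self.waveform.shape[0], dtype=bool)

    @property
    def n_channels(self) -> int:
        return int(self.waveform.shape[0])


def _biphasic(tau: float, half_window: float, fs: float) -> np.ndarray:
    """Biphasic wavelet (Gaussian first derivative), unit peak amplitude."""
    t = np.arange(-half_window, half_window + 0.5 / fs, 1.0 / fs)
    w = -t / tau * np.exp(0.5 - t ** 2 / (2 * tau ** 2))
    return w / np.max(np.abs(w))


def _spatial_weights(center, sigma, grid_shape):
    rows, cols = np.mgrid[0:grid_shape[0], 0:grid_shape[1]]
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return np.exp(-d2 / (2 * sigma ** 2)).ravel()


def make_template(center, amplitude: float = 1.0, tau: float = 0.002,
                  sigma: float = 1.5, half_window: float = 0.025,
                  grid_shape=GRID_SHAPE, fs: float = FS_DEFAULT
                  ) -> MUAPTemplate:
    """Construct a synthetic MUAP: biphasic wavelet x spatial Gaussian."""
    wave = _biphasic(tau, half_window, fs)
    w = _spatial_weights(center, sigma, grid_shape)
    return MUAPTemplate(waveform=amplitude * np.outer(w, wave),
                        center=tuple(center), grid_shape=grid_shape, fs=fs)


def synthesize_muaps_and_emg(trains, duration: float,
                             snr_db: float = 15.0, seed: int = 0,
                             grid_shape=GRID_SHAPE, fs: float = FS_DEFAULT,
                             centers=None, unit_seed: int | None = None):
    """Ground-truth MUAP templates plus the mixed multichannel EMG.

    Each unit receives a biphasic time course scaled per channel by a spatial
    Gaussian at a (seeded) random grid coordinate; the EMG is the sum of
    templates placed at the spike times plus white noise at ``snr_db``
    (signal power over the whole record; ``inf`` disables noise).

    Unit properties (center, amplitude, wavelet width) are drawn from
    ``unit_seed`` -- keep it fixed across trials of the same pool so a unit
    keeps one MUAP, as real units do; ``seed`` drives only the additive
    noise.  ``centers`` overrides the random grid coordinates.
    """
    rng = np.random.default_rng(seed)
    unit_rng = np.random.default_rng(seed if unit_seed is None else unit_seed)
    n_samp = int(round(duration * fs)) + 1
    n_ch = grid_shape[0] * grid_shape[1]
    emg = np.zeros((n_ch, n_samp))
    templates = []
    for tr in trains:
        if unit_seed is not None:
            # properties keyed on (unit_seed, unit_id): stable across trials
            prop_rng = np.random.default_rng(np.random.SeedSequence(
                [unit_seed, tr.unit_id]).generate_state(1)[0])
        else:
            prop_rng = unit_rng
        c = centers[tr.unit_id] if centers is not None else \
            (prop_rng.uniform(1, grid_shape[0] - 2),
             prop_rng.uniform(0.5, grid_shape[1] - 1.5))
        amp = prop_rng.uniform(0.5, 2.0)
        tau = prop_rng.uniform(0.0015, 0.003)
        tpl = make_template(c, amplitude=amp, tau=tau, grid_shape=grid_shape,
                            fs=fs)
        templates.append(tpl)
        half = (tpl.waveform.shape[1] - 1) // 2
        for ts in tr.times:
            k = int(round(ts * fs))
            lo, hi = k - half, k + half + 1
            wlo = max(0, -lo)
            whi = tpl.waveform.shape[1] - max(0, hi - n_samp)
            emg[:, max(lo, 0):min(hi, n_samp)] += tpl.waveform[:, wlo:whi]

    if np.isfinite(snr_db):
        sig_power = float(np.mean(emg ** 2))
        noise_sd = math.sqrt(sig_power / 10 ** (snr_db / 10.0)) \
            if sig_power > 0 else 1.0
        emg = emg + noise_sd * rng.standard_normal(emg.shape)
    return templates, emg
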