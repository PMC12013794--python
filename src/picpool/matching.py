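"""Cross-trial motor-unit matching via MUAP templates.

Each unit's action potential is estimated by spike-triggered averaging of
the multichannel surface EMG; units are matched across trials when the
normalized 2-D cross-correlation between the spatial representations of
their MUAPs exceeds 0.8, and matched chains receive one unique identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import GRID_SHAPE, MUAPTemplate

MATCH_THRESHOLD = 0.8
MAX_LAG_S = 0.005
MIN_COMMON_CHANNELS = 0.75


@dataclass
class MatchResult:
    pairs: list = field(default_factory=list)   # (key_a, key_b, corr)
    matched: list = field(default_factory=list)  # accepted one-to-one pairs
    mu_uid: dict = field(default_factory=dict)   # (trial, unit) -> uid


def spike_triggered_average(emg: np.ndarray, train, fs: float = 2048.0,
                            window_s: float = 0.025, min_spikes: int = 10,
                            grid_shape=GRID_SHAPE,
                            mask: np.ndarray | None = None) -> MUAPTemplate:
    """Per-channel mean of EMG windows centered on the unit's spikes.

    Windows extending beyond the record are dropped and the retained spike
    count recorded; templates built from fewer than ``min_spikes`` windows
    are flagged low-confidence.
    """
    emg = np.asarray(emg, float)
    half = int(round(window_s * fs))
    n_samp = emg.shape[1]
    acc = np.zeros((emg.shape[0], 2 * half + 1))
    count = 0
    for ts in np.asarray(train.times, float):
        k = int(round(ts * fs))
        if k - half < 0 or k + half + 1 > n_samp:
            continue
        acc += emg[:, k - half:k + half + 1]
        count += 1
    wave = acc / count if count else acc
    p2p = wave.max(axis=1) - wave.min(axis=1)
    center = np.unravel_index(int(np.argmax(p2p)), grid_shape)
    return MUAPTemplate(waveform=wave, center=center, grid_shape=grid_shape,
                        mask=mask, fs=fs, n_spikes=count,
                        low_confidence=count < min_spikes)


def xcorr2_normalized(a: MUAPTemplate, b: MUAPTemplate,
                      max_lag_s: float = MAX_LAG_S) -> float:
    """Maximum over time lags of the normalized (channel x time) correlation.

    Both templates are restricted to their common channels, mean-subtracted
    and unit-normalized over the overlapping channel-time block at each lag;
    the result is the peak cosine similarity in [-1, 1].  Channels are
    compared aligned on the grid (no spatial shift search).
    """
    if a.grid_shape != b.grid_shape:
        raise ValueError("templates have mismatched grid geometry")
    common = a.mask & b.mask
    if common.sum() < MIN_COMMON_CHANNELS * common.size:
        raise ValueError("fewer than 75% of channels in common")
    wa = a.waveform[common]
    wb = b.waveform[common]
    n = min(wa.shape[1], wb.shape[1])
    wa, wb = wa[:, :n], wb[:, :n]
    max_lag = int(round(max_lag_s * a.fs))
    best = -1.0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            xa, xb = wa[:, lag:], wb[:, :n - lag]
        else:
            xa, xb = wa[:, :n + lag], wb[:, -lag:]
        xa = xa - xa.mean()
        xb = xb - xb.mean()
        sa = float((xa * xa).sum())
        sb = float((xb * xb).sum())
        if sa == 0 or sb == 0:
            continue
        # single sqrt of the product: identical templates yield exactly 1.0
        best = max(best, float((xa * xb).sum()) / np.sqrt(sa * sb))
    return best


def correlate_all(templates_by_trial: dict, max_lag_s: float = MAX_LAG_S):
    """All cross-trial template correlations.

    ``templates_by_trial`` maps trial_id -> {unit_id: MUAPTemplate}; returns
    a list of ((trial_a, unit_a), (trial_b, unit_b), corr) over every pair of
    distinct trials.
    """
    pairs = []
    trials = sorted(templates_by_trial)
    for i, ta in enumerate(trials):
        for tb in trials[i + 1:]:
            for ua, tpl_a in sorted(templates_by_trial[ta].items()):
                for ub, tpl_b in sorted(templates_by_trial[tb].items()):
                    c = xcorr2_normalized(tpl_a, tpl_b, max_lag_s)
                    pairs.append(((ta, ua), (tb, ub), c))
    return pairs


class _UnionFind(dict):
    def find(self, x):
        while self.setdefault(x, x) != x:
            self[x] = self[self[x]]
            x = self[x]
        return x

    def union(self, a, b):
        self[self.find(a)] = self.find(b)


def assign_matches(pairs, threshold: float = MATCH_THRESHOLD) -> MatchResult:
    """Greedy one-to-one assignment of cross-trial unit pairs.

    Pairs are accepted in descending correlation order (unit-key tie-break,
    so the result is independent of input ordering) when the correlation
    exceeds ``threshold`` and neither endpoint is already matched within that
    trial pair.  Accepted pairs are chained across trials and every chain --
    and every unmatched unit -- receives one unique MU identifier.
    """
    result = MatchResult(pairs=list(pairs))
    order = sorted(pairs, key=lambda p: (-p[2], p[0], p[1]))
    used = set()
    uf = _UnionFind()
    keys = set()
    for ka, kb, corr in pairs:
        keys.add(ka)
        keys.add(kb)
    for ka, kb, corr in order:
        if corr <= threshold:
            break
        pair_trials = (ka[0], kb[0])
        if (pair_trials, ka) in used or (pair_trials, kb) in used:
            continue
        used.add((pair_trials, ka))
        used.add((pair_trials, kb))
        uf.union(ka, kb)
        result.matched.append((ka, kb, corr))
    roots = {}
    for key in sorted(keys):
        r = uf.find(key)
        if r not in roots:
            roots[r] = len(roots)
        result.mu_uid[key] = roots[r]
    return result
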