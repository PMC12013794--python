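import math

import numpy as np
import pytest

from picpool.simulate import (PoolConfig, SpikeTrain, generate_command,
                              make_template, mvt_constant, simulate_pool,
                              synthesize_muaps_and_emg, synthesize_torque,
                              twitch_kernel)
from picpool.matching import xcorr2_normalized


def pool(cmd, **kwargs):
    defaults = dict(seed=0)
    defaults.update(kwargs)
    return simulate_pool(PoolConfig(**defaults), cmd)


class TestSimulatePool:
    def test_zero_hysteresis_symmetry(self, ramp_cmd):
        """Without PIC hysteresis, recruitment and derecruitment torques match."""
        trains, truth = pool(ramp_cmd, hysteresis=0.0, isi_cv=0.0, seed=3)
        for tr in trains:
            if tr.n_spikes < 2:
                continue
            assert ramp_cmd.drive_at(tr.times[0]) == pytest.approx(
                ramp_cmd.drive_at(tr.times[-1]), abs=1e-9)

    def test_cap_unit_discharges_through_plateau_two(self, sombrero_cmd):
        # theta = 15, effective Delta = 6: release level 9% is never reached
        cfg = PoolConfig(n_units=1, custom_thresholds=(15.0,),
                         hysteresis=6.0, isi_cv=0.0, seed=0)
        trains, truth = simulate_pool(cfg, sombrero_cmd)
        assert truth.categories[0] == "cap"
        assert truth.t_derec[0] == sombrero_cmd.t_end
        assert trains[0].times[-1] == pytest.approx(sombrero_cmd.t_end)

    def test_true_delta_f_product(self, ramp_cmd):
        """Ground-truth Delta-F = reporter gain x test hysteresis x length factor."""
        cfg = PoolConfig(n_units=3, custom_thresholds=(5.0, 10.0, 15.0),
                         gain=1.5, hysteresis=(0.0, 0.0, 2.0),
                         length_factor=1.0, isi_cv=0.0, seed=0)
        trains, truth = simulate_pool(cfg, ramp_cmd)
        assert truth.true_delta_f(test=2, reporter=0) == pytest.approx(3.0)
        # brute-force check: read the reporter's true rate at the test
        # unit's landmarks
        r_rec = truth.rate_at(0, truth.t_rec[2])
        r_derec = truth.rate_at(0, truth.t_derec[2])
        assert float(r_rec - r_derec) == pytest.approx(3.0)

    def test_unreachable_unit_has_empty_train(self, ramp_cmd):
        cfg = PoolConfig(n_units=2, custom_thresholds=(10.0, 50.0), seed=0)
        trains, truth = simulate_pool(cfg, ramp_cmd)
        assert trains[1].n_spikes == 0
        assert np.isnan(truth.t_rec[1])
        assert truth.categories[1] is None

    def test_determinism(self, sombrero_cmd):
        a, _ = pool(sombrero_cmd, seed=11)
        b, _ = pool(sombrero_cmd, seed=11)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.times, tb.times)

    def test_different_seeds_differ(self, sombrero_cmd):
        a, _ = pool(sombrero_cmd, seed=11, isi_cv=0.2)
        b, _ = pool(sombrero_cmd, seed=12, isi_cv=0.2)
        assert any(not np.array_equal(ta.times, tb.times)
                   for ta, tb in zip(a, b))

    @pytest.mark.parametrize("delta", [0.0, 1.0, 3.0, 6.0])
    def test_hysteresis_monotonicity(self, ramp_cmd, delta):
        """More hysteresis never shortens discharge or shrinks true Delta-F."""
        base_trains, base = pool(ramp_cmd, hysteresis=0.0, isi_cv=0.0)
        _, truth = pool(ramp_cmd, hysteresis=delta, isi_cv=0.0)
        rec = base.recruited()
        assert np.all(truth.t_derec[rec] >= base.t_derec[rec] - 1e-12)
        assert truth.true_delta_f(rec[-1], rec[0]) >= 0

    def test_short_muscle_increases_cap_count(self, sombrero_cmd):
        counts = {}
        for lf in (1.0, 1.5):
            n_caps = 0
            for seed in range(5):
                _, truth = pool(sombrero_cmd, hysteresis=3.0,
                                length_factor=lf, isi_cv=0.1, seed=seed)
                n_caps += sum(c == "cap" for c in truth.categories if c)
            counts[lf] = n_caps
        assert counts[1.5] > counts[1.0]

    def test_rate_matches_drive_excess(self, ramp_cmd):
        """Deterministic ISIs reproduce rate_min + gain * excess drive."""
        cfg = PoolConfig(n_units=1, custom_thresholds=(10.0,), gain=2.0,
                         hysteresis=0.0, isi_cv=0.0, rate_min=5.0, seed=0)
        trains, truth = simulate_pool(cfg, ramp_cmd)
        t = trains[0].times
        mid = (t[:-1] + t[1:]) / 2
        inst = 1.0 / np.diff(t)
        expected = 5.0 + 2.0 * (ramp_cmd.drive_at(mid) - 10.0)
        # interval-averaged rates track the instantaneous profile closely
        interior = slice(1, -1)
        assert np.allclose(inst[interior], expected[interior], rtol=0.05)


class TestSynthesizeTorque:
    def test_single_twitch_peak(self, ramp_cmd):
        cfg = PoolConfig(n_units=1, custom_thresholds=(10.0,), seed=0,
                         twitch_tc_range=(100 / 2048, 100 / 2048))
        _, truth = simulate_pool(cfg, ramp_cmd)
        train = SpikeTrain(unit_id=0, times=np.array([2.0]))
        trace = synthesize_torque([train], truth, noise_sd=0.0,
                                  rescale=False)
        k = int(np.argmax(trace.torque_pct))
        # peak lags the spike by exactly Tc
        assert trace.t[k] - 2.0 == pytest.approx(truth.twitch_tc[0],
                                                 abs=1.5 / 2048)

    def test_empty_spike_set_zero_trace(self, ramp_cmd):
        _, truth = pool(ramp_cmd)
        empty = [SpikeTrain(unit_id=0, times=np.array([]))]
        trace = synthesize_torque(empty, truth, noise_sd=0.0, rescale=False)
        assert np.allclose(trace.torque_raw, 0.0)

    def test_distant_twitches_superpose(self, ramp_cmd):
        cfg = PoolConfig(n_units=1, custom_thresholds=(10.0,), seed=0)
        _, truth = simulate_pool(cfg, ramp_cmd)
        tc = truth.twitch_tc[0]
        train = SpikeTrain(unit_id=0, times=np.array([2.0, 2.0 + 10 * tc]))
        one = synthesize_torque([SpikeTrain(unit_id=0,
                                            times=np.array([2.0]))],
                                truth, noise_sd=0.0, rescale=False)
        two = synthesize_torque([train], truth, noise_sd=0.0, rescale=False)
        assert np.max(two.torque_raw) == pytest.approx(
            np.max(one.torque_raw), rel=1e-3)

    def test_torque_conservation(self, ramp_cmd):
        """Integral of noiseless torque = n_spikes x twitch integral."""
        cfg = PoolConfig(n_units=2, custom_thresholds=(5.0, 12.0),
                         isi_cv=0.0, seed=0)
        trains, truth = simulate_pool(cfg, ramp_cmd)
        trace = synthesize_torque(trains, truth, noise_sd=0.0, rescale=False)
        area = np.trapezoid(trace.torque_raw, trace.t)
        expected = sum(
            tr.n_spikes * truth.twitch_peak[tr.unit_id]
            * truth.twitch_tc[tr.unit_id] * math.e
            for tr in trains)
        expected *= trace.mvt / mvt_constant(truth)
        # late spikes lose part of their twitch past the record end
        assert area == pytest.approx(expected, rel=0.02)

    def test_twitch_kernel_closed_form(self):
        k = twitch_kernel(2.0, 0.05, fs=2048)
        t = np.arange(k.size) / 2048
        assert np.allclose(k, 2.0 * (t / 0.05) * np.exp(1 - t / 0.05))


class TestSynthesizeEMG:
    def test_noiseless_emg_reconstructs_template(self):
        train = SpikeTrain(unit_id=0, times=np.array([1.0, 3.0, 5.0]))
        tpls, emg = synthesize_muaps_and_emg([train], duration=6.0,
                                             snr_db=np.inf, seed=4)
        half = (tpls[0].waveform.shape[1] - 1) // 2
        k = int(round(3.0 * 2048))
        window = emg[:, k - half:k + half + 1]
        assert np.allclose(window, tpls[0].waveform)

    def test_same_seed_bit_identical(self):
        train = SpikeTrain(unit_id=0, times=np.array([0.5, 1.0]))
        _, a = synthesize_muaps_and_emg([train], 2.0, snr_db=10, seed=9)
        _, b = synthesize_muaps_and_emg([train], 2.0, snr_db=10, seed=9)
        assert np.array_equal(a, b)

    def test_distant_units_decorrelated(self):
        """Templates 6+ electrodes apart correlate below the match threshold."""
        a = make_template((2.0, 1.0))
        b = make_template((9.0, 3.0))
        assert xcorr2_normalized(a, b) < 0.8
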