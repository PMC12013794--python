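import numpy as np
import pytest

from picpool import preprocess, sombrero
from picpool.simulate import PoolConfig, SpikeTrain, simulate_pool


def train(times):
    return SpikeTrain(unit_id=0, times=np.asarray(times, float))


class TestDischargeEnd:
    def test_no_gap_ends_at_last_spike(self):
        t = np.arange(0, 5, 0.1)
        assert sombrero.discharge_end(train(t)) == pytest.approx(t[-1])

    def test_long_gap_terminates(self):
        t = np.r_[np.arange(0, 20.01, 0.1), 21.5, 21.6]
        assert sombrero.discharge_end(train(t)) == pytest.approx(20.0)

    def test_gap_of_exactly_one_second_breaks(self):
        t = np.array([0.0, 0.5, 1.0, 2.0, 2.1])
        assert sombrero.discharge_end(train(t)) == pytest.approx(1.0)

    def test_gap_just_under_one_second_continues(self):
        t = np.array([0.0, 0.5, 1.0, 1.999, 2.1])
        assert sombrero.discharge_end(train(t)) == pytest.approx(2.1)


class TestClassification:
    @pytest.fixture
    def windows(self, sombrero_cmd):
        return preprocess.segment_plateaus(sombrero_cmd)

    def test_plateau_one_recruit_is_brim(self, windows):
        cats = sombrero.classify_units([train(np.arange(2, 30, 0.1))],
                                       windows)
        assert cats[0].category == "brim"

    def test_ramp_recruit_ending_in_ramp_is_button(self, windows):
        cats = sombrero.classify_units([train(np.arange(14, 20, 0.1))],
                                       windows)
        assert cats[0].category == "button"

    def test_ramp_recruit_reaching_plateau_two_is_cap(self, windows):
        cats = sombrero.classify_units([train(np.arange(14, 30, 0.1))],
                                       windows)
        assert cats[0].category == "cap"

    def test_plateau_two_recruit_is_other(self, windows):
        cats = sombrero.classify_units([train(np.arange(25, 30, 0.1))],
                                       windows)
        assert cats[0].category == "other"

    def test_silent_unit_is_none(self, windows):
        cats = sombrero.classify_units([train([])], windows)
        assert cats[0].category == "none"

    def test_noiseless_simulation_matches_ground_truth(self, sombrero_cmd,
                                                       windows):
        for seed in range(5):
            cfg = PoolConfig(seed=seed, isi_cv=0.0, hysteresis=3.0,
                             length_factor=1.5)
            trains, truth = simulate_pool(cfg, sombrero_cmd)
            cats = sombrero.classify_units(trains, windows)
            for c in cats:
                assert c.category == (truth.categories[c.unit_id] or "none")


class TestSustainedDuration:
    def test_worked_ramp_arithmetic(self, sombrero_cmd):
        """Recruited at 15% on the ascent; crossing at 15% on the descent.

        sombrero(10, 30, 3, 10): recruitment at 15% MVT happens at
        t = 10 + 5/3 s; the descending 15% crossing is at 16.667 + 5 s.
        """
        spikes = np.arange(10 + 5 / 3, 33.0, 0.1)
        s = sombrero.sustained_duration(train(spikes), tq_rec=15.0,
                                        cmd=sombrero_cmd)
        assert s.t_theoretical_derec == pytest.approx(16.6667 + 5.0,
                                                      abs=1e-3)
        assert s.sustained_dur == pytest.approx(
            spikes[-1] - (16.6667 + 5.0), abs=1e-3)

    def test_derecruited_at_crossing_gives_zero(self, sombrero_cmd):
        t_cross = 16 + 2 / 3 + 5.0
        spikes = np.arange(10 + 5 / 3, t_cross + 1e-9, 0.05)
        spikes[-1] = t_cross
        s = sombrero.sustained_duration(train(spikes), tq_rec=15.0,
                                        cmd=sombrero_cmd)
        assert s.sustained_dur == pytest.approx(0.0, abs=1e-6)

    def test_no_crossing_flagged(self, command_trace, sombrero_cmd):
        # recruitment torque below the final plateau level never re-crosses
        trace = command_trace(sombrero_cmd)
        s = sombrero.sustained_duration(train(np.arange(11, 30, 0.1)),
                                        tq_rec=8.0, trace=trace)
        assert s.no_crossing

    def test_outside_ramp_rejected(self, sombrero_cmd):
        w = preprocess.segment_plateaus(sombrero_cmd)
        with pytest.raises(ValueError):
            sombrero.sustained_duration(train(np.arange(2, 30, 0.1)),
                                        tq_rec=10.0, cmd=sombrero_cmd,
                                        windows=w)


class TestProportionSustained:
    def make(self, n_cap_long, n_cap_short, n_button, n_brim):
        cats, sus, uid = [], [], 0
        for dur, n_caps in ((5.0, n_cap_long), (1.0, n_cap_short)):
            for _ in range(n_caps):
                cats.append(sombrero.MUCategory(uid, "cap", 15.0, 30.0))
                sus.append(sombrero.SustainedDischarge(uid, 20.0, 20 + dur,
                                                       dur))
                uid += 1
        for _ in range(n_button):
            cats.append(sombrero.MUCategory(uid, "button", 15.0, 20.0))
            uid += 1
        for _ in range(n_brim):
            cats.append(sombrero.MUCategory(uid, "brim", 1.0, 33.0))
            uid += 1
        return cats, sus

    def test_ramp_denominator(self):
        cats, sus = self.make(3, 1, 6, 5)
        # 3 caps > 2 s out of 10 ramp-recruited units (4 cap + 6 button)
        assert sombrero.proportion_sustained(cats, sus) == pytest.approx(0.3)

    def test_cap_brim_denominator_option(self):
        cats, sus = self.make(3, 1, 6, 5)
        assert sombrero.proportion_sustained(
            cats, sus, denominator="cap+brim") == pytest.approx(3 / 9)

    def test_no_caps_zero(self):
        cats, sus = self.make(0, 0, 4, 2)
        assert sombrero.proportion_sustained(cats, sus) == 0.0

    def test_empty_denominator_flagged(self):
        cats, sus = self.make(0, 0, 0, 3)
        assert sombrero.proportion_sustained(cats, sus) is None

    def test_bounded_and_label_invariant(self):
        cats, sus = self.make(2, 2, 3, 1)
        p = sombrero.proportion_sustained(cats, sus)
        assert 0.0 <= p <= 1.0
        # relabeling unit ids consistently leaves the proportion unchanged
        remap = {c.unit_id: 100 - c.unit_id for c in cats}
        cats2 = [sombrero.MUCategory(remap[c.unit_id], c.category, c.t_rec,
                                     c.discharge_end) for c in cats]
        sus2 = [sombrero.SustainedDischarge(remap[s.unit_id],
                                            s.t_theoretical_derec,
                                            s.t_discharge_end,
                                            s.sustained_dur) for s in sus]
        assert sombrero.proportion_sustained(cats2, sus2) == pytest.approx(p)


class TestPlateauRateDelta:
    def test_constant_rate_delta_zero(self, sombrero_cmd, make_curve):
        w = preprocess.segment_plateaus(sombrero_cmd)
        t = np.linspace(0, sombrero_cmd.t_end, 3000)
        sm = {0: make_curve(t, np.full_like(t, 11.0))}
        out = sombrero.plateau_rate_delta(sm, w)
        assert out["delta_pps"][0] == pytest.approx(0.0, abs=1e-9)

    def test_known_rate_drop(self, sombrero_cmd, make_curve):
        w = preprocess.segment_plateaus(sombrero_cmd)
        t = np.linspace(0, sombrero_cmd.t_end, 3000)
        rate = np.where(t < w.ramp[0], 12.0,
                        np.where(t >= w.plateau_two[0], 10.0, 11.0))
        out = sombrero.plateau_rate_delta({0: make_curve(t, rate)}, w)
        assert out["delta_pps"][0] == pytest.approx(-2.0, abs=0.02)

    def test_inactive_unit_excluded_with_reason(self, sombrero_cmd,
                                                make_curve):
        w = preprocess.segment_plateaus(sombrero_cmd)
        t = np.linspace(0, 9.0, 500)  # ends before plateau two
        out = sombrero.plateau_rate_delta({7: make_curve(t, t + 10)}, w)
        assert 7 not in out["delta_pps"]
        assert out["excluded"][7] == "inactive_in_plateau_two"
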