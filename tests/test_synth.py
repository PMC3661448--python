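import math

import numpy as np
import pandas as pd
import pytest

from epgkit import (
    ConditionSchedule,
    PumpKernelSpec,
    ScheduleEffect,
    draw_worm,
    generate_cohort,
    generate_tail_trace,
    generate_trace,
    load_preset,
    available_presets,
)
from epgkit.synth import DEFAULT_SNR, PhenotypePreset, TailPreset


class TestPresets:
    def test_shipped_preset_names(self):
        names = available_presets()
        for expected in ("wt_basal_chip", "wt_5ht_chip", "wt_basal_conventional",
                         "wt_5ht_conventional", "eat4_chip", "eat4_conventional",
                         "tail"):
            assert expected in names

    def test_shipped_values(self):
        wt = load_preset("wt_basal_chip")
        assert wt.freq_mean == 0.075
        assert wt.dur_mean == 0.116
        assert wt.p_rate == 1.788
        assert wt.amp_pp_mean == 4.410
        assert wt.e_amp_mean == 0.257
        ht = load_preset("wt_5ht_chip")
        assert (ht.freq_mean, ht.dur_mean, ht.p_rate) == (3.467, 0.101, 0.126)
        assert (ht.amp_pp_mean, ht.e_amp_mean) == (8.370, 1.753)
        e4 = load_preset("eat4_chip")
        assert (e4.freq_mean, e4.dur_mean, e4.p_rate) == (0.090, 0.172, 0.103)
        assert e4.re_ratio_mean == 1.491

    def test_tail_preset_kind(self):
        assert isinstance(load_preset("tail"), TailPreset)

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="wt_basal_chip"):
            load_preset("nonsense")

    def test_invalid_preset_values(self):
        with pytest.raises(ValueError):
            PhenotypePreset(name="bad", freq_mean=1.0, dur_mean=-0.1, p_rate=0.1,
                            amp_pp_mean=4.0, e_amp_mean=0.2, re_ratio_mean=1.2)
        with pytest.raises(ValueError):
            PhenotypePreset(name="bad", freq_mean=1.0, dur_mean=0.1, p_rate=0.1,
                            amp_pp_mean=4.0, e_amp_mean=0.2, re_ratio_mean=1.2,
                            worm_cv=1.5)


class TestDrawWorm:
    def test_zero_cv_degenerate(self, wt_basal):
        p = PhenotypePreset(**{**wt_basal.__dict__, "worm_cv": 0.0, "name": "d"})
        w = draw_worm(p, seed=0)
        assert w.freq == p.freq_mean
        assert w.dur == p.dur_mean
        assert w.amp_pp == p.amp_pp_mean

    def test_determinism(self, wt_basal):
        assert draw_worm(wt_basal, seed=42) == draw_worm(wt_basal, seed=42)

    def test_monte_carlo_cv(self, wt_basal):
        # 1000 draws at worm_cv 0.1: sample CV of freq within 0.1 +/- 0.02
        p = PhenotypePreset(**{**wt_basal.__dict__, "worm_cv": 0.1, "name": "mc"})
        freqs = np.array([draw_worm(p, seed=s).freq for s in range(1000)])
        cv = freqs.std(ddof=1) / freqs.mean()
        assert abs(cv - 0.1) < 0.02


class TestGenerateTrace:
    def test_extremum_scan_oracle(self, clean_5ht_trace):
        # Independent oracle: within each ground-truth pump window the raw
        # trace's extremum must sit within one sample of the truth time.
        trace, truth = clean_5ht_trace
        rate = trace.sampling_rate
        for _, grp in truth.events.groupby("pump_index"):
            for _, row in grp.iterrows():
                t, a = row["time_s"], row["amplitude_mV"]
                i0 = trace.time_to_index(t - 0.003)
                i1 = trace.time_to_index(t + 0.003) + 1
                seg = trace.samples[i0:i1]
                ext = i0 + (np.argmax(seg) if a > 0 else np.argmin(seg))
                assert abs(ext / rate - t) <= 1.0 / rate + 1e-9

    def test_zero_frequency_flat(self, wt_basal):
        p = PhenotypePreset(**{**wt_basal.__dict__, "freq_mean": 0.0, "name": "z"})
        trace, truth = generate_trace(p, duration=10, snr=math.inf,
                                      drift=False, seed=0)
        assert np.all(trace.samples == 0.0)
        assert truth.n_pumps == 0

    def test_5ht_pump_count_in_poisson_range(self, wt_5ht):
        _, truth = generate_trace(wt_5ht, duration=120, seed=3)
        expected = 3.467 * 120
        assert abs(truth.n_pumps - expected) <= 4 * math.sqrt(expected)

    def test_ground_truth_ordering(self, wt_basal):
        _, truth = generate_trace(wt_basal, duration=300, seed=5)
        truth.check_ordering()

    def test_inter_pump_gap_exactly_zero(self, wt_5ht):
        trace, truth = generate_trace(wt_5ht, duration=15, snr=math.inf,
                                      drift=False, seed=4)
        kern = PumpKernelSpec()
        rate = trace.sampling_rate
        tR = truth.times("R")
        tE = truth.times("E")
        for r_prev, e_next in zip(tR, tE[1:]):
            i0 = trace.time_to_index(r_prev + kern.tail_margin) + 2
            i1 = trace.time_to_index(e_next - kern.head_margin) - 2
            if i1 > i0:
                assert np.all(trace.samples[i0:i1] == 0.0)

    def test_seed_bit_identical(self, wt_5ht):
        t1, g1 = generate_trace(wt_5ht, duration=30, seed=11)
        t2, g2 = generate_trace(wt_5ht, duration=30, seed=11)
        assert np.array_equal(t1.samples, t2.samples)
        assert g1.events.equals(g2.events)

    def test_long_run_frequency_converges(self, wt_5ht):
        # >= 500 expected pumps: empirical rate within 5% relative
        _, truth = generate_trace(wt_5ht, duration=200, seed=6)
        emp = truth.n_pumps / 200.0
        assert abs(emp - 3.467) / 3.467 < 0.05

    def test_p_rate_converges(self, wt_basal):
        # basal preset has the highest P intensity; ~500 pumps
        p = PhenotypePreset(**{**wt_basal.__dict__, "freq_mean": 1.0, "name": "f1"})
        _, truth = generate_trace(p, duration=520, seed=7)
        n_p = (truth.events["event_type"] == "P").sum()
        assert truth.n_pumps >= 450
        assert abs(n_p / truth.n_pumps - 1.788) / 1.788 < 0.10

    def test_snr_zero_rejected(self, wt_basal):
        with pytest.raises(ValueError):
            generate_trace(wt_basal, duration=10, snr=0.0, seed=0)

    def test_incompatible_kernel_rejected(self, wt_5ht):
        kern = PumpKernelSpec(E_width=0.06)
        with pytest.raises(ValueError, match="incompatible"):
            generate_trace(wt_5ht, kernel=kern, duration=10, seed=0)

    def test_noise_sigma_matches_snr(self, wt_basal):
        p = PhenotypePreset(**{**wt_basal.__dict__, "freq_mean": 0.0,
                               "worm_cv": 0.0, "name": "n"})
        trace, _ = generate_trace(p, duration=30, snr=10.0, drift=False, seed=8)
        assert trace.samples.std() == pytest.approx(4.410 / 10.0, rel=0.05)


class TestScheduleEffects:
    def test_multipliers_before_onset(self):
        eff = ScheduleEffect("5HT", freq_mult=40.0, onset_latency=300.0,
                             time_constant=300.0, persists=True)
        assert eff.multipliers_at(100.0, 0.0, 600.0) == (1.0, 1.0, 1.0, 1.0)

    def test_step_effect_inside_interval_only(self):
        eff = ScheduleEffect("light_on", freq_mult=1.5, dur_mult=0.8)
        assert eff.multipliers_at(10.0, 0.0, 20.0)[0] == pytest.approx(1.5)
        assert eff.multipliers_at(25.0, 0.0, 20.0)[0] == 1.0

    def test_persistent_effect_survives_interval(self):
        eff = ScheduleEffect("ethanol", freq_mult=0.5, time_constant=0.0,
                             persists=True)
        assert eff.multipliers_at(100.0, 0.0, 20.0)[0] == pytest.approx(0.5)

    def test_exponential_approach(self):
        eff = ScheduleEffect("5HT", freq_mult=41.0, onset_latency=0.0,
                             time_constant=100.0, persists=True)
        f, _, _, _ = eff.multipliers_at(100.0, 0.0, 1e9)
        assert f == pytest.approx(1 + 40 * (1 - math.exp(-1)))


class TestTailTrace:
    def test_amplitude_below_quarter_of_head(self, wt_basal):
        trace = generate_tail_trace(60, seed=1)
        assert np.ptp(trace.samples) < 0.25 * wt_basal.amp_pp_mean

    def test_no_negative_transient_noise_free(self):
        trace = generate_tail_trace(60, seed=1, snr=math.inf)
        assert trace.samples.min() >= 0.0

    def test_determinism(self):
        a = generate_tail_trace(30, seed=9)
        b = generate_tail_trace(30, seed=9)
        assert np.array_equal(a.samples, b.samples)


class TestCohort:
    def test_fig8_composition(self, wt_basal, eat4):
        members = generate_cohort([(wt_basal, 7), (eat4, 3)], duration=30,
                                  seed=0, rate=500)
        assert len(members) == 10
        assert sum(m.true_label == "eat4_chip" for m in members) == 3

    def test_single_entry(self, wt_basal, eat4):
        members = generate_cohort([(wt_basal, 0), (eat4, 1)], duration=30,
                                  seed=0, rate=500)
        assert len(members) == 1
        assert members[0].true_label == "eat4_chip"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort([], duration=30, seed=0)

    def test_seed_changes_shuffle_not_labels(self, wt_basal, eat4):
        a = generate_cohort([(wt_basal, 5), (eat4, 5)], duration=20, seed=1, rate=500)
        b = generate_cohort([(wt_basal, 5), (eat4, 5)], duration=20, seed=2, rate=500)
        assert [m.true_label for m in a] != [m.true_label for m in b]
        assert sorted(m.true_label for m in a) == sorted(m.true_label for m in b)
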