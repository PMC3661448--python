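import math

import numpy as np
import pytest

from epgkit import (
    ConditionSchedule,
    EPGParameters,
    ScheduleEffect,
    compare_groups,
    compute_parameters,
    detect_pumps,
    epoch_summary,
    frequency_timecourse,
    generate_trace,
    highpass,
    load_preset,
)
from epgkit.detect import EventTable, PumpEvent
from epgkit.synth import PhenotypePreset, draw_worm


def _table(pumps, analyzed_s):
    return EventTable(pumps, analyzed_s=analyzed_s, noise_sigma=0.1)


def _pump(t_E, a_E, t_R, a_R, n_P=0, a_e=None, t_e=None):
    t_P = list(np.linspace(t_E + 0.02, t_R - 0.02, n_P)) if n_P else []
    return PumpEvent(t_E=t_E, a_E=a_E, t_R=t_R, a_R=a_R,
                     t_e=t_e, a_e=a_e, t_P=t_P, a_P=[-1.0] * n_P)


class TestComputeParameters:
    def test_single_pump_arithmetic(self):
        ev = _table([_pump(1.000, 3.0, 1.116, -2.0)], analyzed_s=10.0)
        p = compute_parameters(ev)
        assert p.amp_pp == pytest.approx(5.0)
        assert p.duration == pytest.approx(0.116)
        assert p.re_ratio == pytest.approx(2.0 / 3.0, rel=1e-6)
        assert p.frequency == pytest.approx(0.1)

    def test_re_interval(self):
        ev = _table([_pump(9.0, 3.0, 10.0, -2.0), _pump(34.0, 3.0, 34.1, -2.0)],
                    analyzed_s=60.0)
        p = compute_parameters(ev)
        assert p.re_interval == pytest.approx(24.0)

    def test_empty_table_all_missing(self):
        p = compute_parameters(_table([], analyzed_s=10.0))
        assert p.n_pumps == 0
        assert p.duration is None
        assert p.amp_pp is None
        assert p.e_amp is None

    def test_e_amp_only_over_detected(self):
        ev = _table([_pump(1.0, 3.0, 1.1, -2.0, a_e=0.3, t_e=0.975),
                     _pump(5.0, 3.0, 5.1, -2.0)], analyzed_s=10.0)
        p = compute_parameters(ev)
        assert p.e_amp == pytest.approx(0.3)

    def test_p_per_pump(self):
        ev = _table([_pump(1.0, 3.0, 1.1, -2.0, n_P=2),
                     _pump(5.0, 3.0, 5.1, -2.0, n_P=1)], analyzed_s=10.0)
        assert compute_parameters(ev).p_per_pump == pytest.approx(1.5)

    def test_permutation_invariant(self):
        pumps = [_pump(t, 3.0, t + 0.1, -2.0) for t in (1.0, 5.0, 9.0)]
        a = compute_parameters(_table(pumps, 20.0))
        b = compute_parameters(_table(pumps[::-1], 20.0))
        assert a == b

    def test_re_interval_excludes_schedule_boundary(self, wt_5ht):
        from epgkit.trace import Trace

        sched = ConditionSchedule([(0.0, 4.0, "baseline"), (4.0, 10.0, "5HT")])
        trace = Trace(np.zeros(20000), 2000.0, schedule=sched)
        ev = _table([_pump(1.0, 3.0, 1.1, -2.0), _pump(3.0, 3.0, 3.1, -2.0),
                     _pump(6.0, 3.0, 6.1, -2.0)], analyzed_s=10.0)
        p = compute_parameters(ev, trace)
        # the 3.1 -> 6.0 gap spans the 4.0 s boundary and is dropped
        assert p.re_interval == pytest.approx(3.0 - 1.1)


class TestTimeCourse:
    def test_uniform_pumps(self):
        pumps = [_pump(5.0 + 10.0 * i, 3.0, 5.1 + 10.0 * i, -2.0)
                 for i in range(10)]
        tc = frequency_timecourse(_table(pumps, 100.0), 10.0,
                                  t_start=0.0, t_end=100.0)
        assert np.allclose(tc.frequency, 0.1)
        assert tc.counts.sum() == 10

    def test_empty_table(self):
        tc = frequency_timecourse(_table([], 50.0), 10.0, t_start=0.0, t_end=50.0)
        assert np.all(tc.frequency == 0.0)
        assert np.all(np.isnan(tc.duration))

    def test_bin_count_sums_to_n_pumps(self, noisy_5ht_trace):
        trace, _ = noisy_5ht_trace
        events = detect_pumps(trace)
        tc = frequency_timecourse(events, 7.0)
        assert tc.counts.sum() == len(events)

    def test_washin_frequency_rises(self, wt_basal):
        sched = ConditionSchedule([(30.0, 300.0, "5HT")])
        eff = {"5HT": ScheduleEffect("5HT", freq_mult=40.0, dur_mult=0.87,
                                     p_rate_mult=0.07, onset_latency=20.0,
                                     time_constant=40.0, persists=True)}
        trace, _ = generate_trace(wt_basal, schedule=sched, effects=eff,
                                  duration=300, seed=9)
        events = detect_pumps(highpass(trace))
        tc = frequency_timecourse(events, 30.0, t_start=0.0, t_end=300.0)
        assert tc.frequency[-2] > tc.frequency[0]

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            frequency_timecourse(_table([], 10.0), 0.0)


@pytest.fixture(scope="module")
def light_run(wt_5ht):
    sched = ConditionSchedule([(0.0, 120.0, "baseline"),
                               (120.0, 270.0, "light_on")])
    trace, _ = generate_trace(wt_5ht, schedule=sched, duration=270, seed=9)
    events = detect_pumps(highpass(trace))
    tc = frequency_timecourse(events, 30.0, t_start=0.0, t_end=270.0)
    return tc, sched


class TestEpochSummary:
    def test_light_raises_rate_and_shortens_pumps(self, light_run):
        tc, sched = light_run
        summ = epoch_summary(tc, sched).set_index("condition")
        assert summ.loc["light_on", "mean_frequency"] > \
            summ.loc["baseline", "mean_frequency"]
        assert summ.loc["light_on", "mean_duration"] < \
            summ.loc["baseline", "mean_duration"]

    def test_no_retinal_control_flat(self, wt_5ht):
        # all multipliers 1: before/during difference within 2x simulation s.e.
        sched = ConditionSchedule([(0.0, 120.0, "baseline"),
                                   (120.0, 270.0, "light_on")])
        eff = {"light_on": ScheduleEffect("light_on")}  # all multipliers 1
        diffs = []
        for seed in range(6):
            trace, _ = generate_trace(wt_5ht, schedule=sched, effects=eff,
                                      duration=270, seed=40 + seed)
            events = detect_pumps(highpass(trace))
            tc = frequency_timecourse(events, 30.0, t_start=0.0, t_end=270.0)
            s = epoch_summary(tc, sched).set_index("condition")
            diffs.append(s.loc["light_on", "mean_frequency"] -
                         s.loc["baseline", "mean_frequency"])
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / math.sqrt(len(diffs))
        assert abs(diffs.mean()) < 2 * se + 0.1

    def test_single_interval(self):
        pumps = [_pump(5.0, 3.0, 5.1, -2.0)]
        tc = frequency_timecourse(_table(pumps, 60.0), 10.0,
                                  t_start=0.0, t_end=60.0)
        summ = epoch_summary(tc, ConditionSchedule([(0.0, 60.0, "baseline")]))
        assert len(summ) == 1

    def test_zero_bin_interval_warns(self):
        tc = frequency_timecourse(_table([], 60.0), 10.0, t_start=0.0, t_end=60.0)
        with pytest.warns(UserWarning):
            summ = epoch_summary(
                tc, ConditionSchedule([(60.0, 60.5, "light_on")]))
        assert np.isnan(summ["mean_frequency"].iloc[0])


def _params(worm_id, duration):
    return EPGParameters(worm_id=worm_id, n_pumps=50, analyzed_s=100.0,
                         duration=duration, p_per_pump=1.0, amp_pp=4.0,
                         frequency=0.5, re_ratio=1.2)


class TestCompareGroups:
    def test_identical_groups(self):
        a = [_params(f"a{i}", 0.116) for i in range(5)]
        b = [_params(f"b{i}", 0.116) for i in range(5)]
        cmp = compare_groups(a, b, "duration")
        assert cmp.t_stat == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0)

    def test_n1_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([_params("a", 0.1)], [_params("b", 0.2)] * 3,
                           "duration")

    def test_missing_metric_excluded_with_warning(self):
        a = [_params(f"a{i}", 0.116) for i in range(3)]
        a.append(EPGParameters(worm_id="a3", n_pumps=0))
        b = [_params(f"b{i}", 0.172) for i in range(3)]
        with pytest.warns(UserWarning, match="a3"):
            cmp = compare_groups(a, b, "duration")
        assert cmp.n_a == 3

    def test_power_at_published_effect_size(self, wt_basal, eat4):
        # per-worm mean durations drawn from the two presets, n = 10 each:
        # Welch p < 0.01 in >= 95% of replicates
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            groups = []
            for preset in (wt_basal, eat4):
                ws = []
                for i in range(10):
                    w = draw_worm(preset, rng)
                    noise = rng.normal(0, preset.dur_mean * preset.dur_cv /
                                       math.sqrt(40))
                    ws.append(EPGParameters(worm_id=f"{preset.name}{i}",
                                            n_pumps=40, analyzed_s=400.0,
                                            duration=w.dur + noise))
                groups.append(ws)
            cmp = compare_groups(groups[0], groups[1], "duration")
            hits += cmp.p_value < 0.01
        assert hits / n_rep >= 0.95
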