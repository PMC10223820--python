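"""CGM parsing and the sustained-excursion detector."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import (DAY, MIDNIGHT, assert_same_excursions,
                     brute_force_excursions, make_trace, random_trace)
from trescore.cgm import (daily_glucose_events, detect_excursions,
                          exclude_sleep_onsets, read_cgm)


def grid(n, start=240.0, step=15.0):
    return start + step * np.arange(n)


class TestReadCGM:
    def test_regular_day(self, tmp_path):
        rows = ["participant,timestamp,glucose_mmol_l"]
        rows += [f"P01,2022-03-01 {h:02d}:{m:02d},5.0"
                 for h in range(24) for m in (0, 15, 30, 45)]
        p = tmp_path / "c.csv"
        p.write_text("\n".join(rows) + "\n")
        trace = read_cgm(p)
        assert len(trace) == 96
        assert trace.gaps() == []

    def test_duplicate_timestamps_collapse_to_mean(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("participant,timestamp,glucose_mmol_l\n"
                     "P01,2022-03-01 08:00,5.0\n"
                     "P01,2022-03-01 08:00,6.0\n"
                     "P01,2022-03-01 08:15,5.2\n")
        trace = read_cgm(p)
        assert len(trace) == 2
        assert trace.glucose[0] == pytest.approx(5.5)

    def test_nonpositive_glucose_rejected_with_line(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("participant,timestamp,glucose_mmol_l\n"
                     "P01,2022-03-01 08:00,5.0\n"
                     "P01,2022-03-01 08:15,-1.0\n")
        with pytest.raises(ValueError, match=r"\[3\]"):
            read_cgm(p)

    def test_gap_derivable(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("participant,timestamp,glucose_mmol_l\n"
                     "P01,2022-03-01 08:00,5.0\n"
                     "P01,2022-03-01 12:00,5.0\n")
        assert len(read_cgm(p).gaps()) == 1

    def test_empty_errors(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("participant,timestamp,glucose_mmol_l\n")
        with pytest.raises(ValueError, match="no records"):
            read_cgm(p)


class TestDetectExcursions:
    def test_flat_trace_nothing(self, targets):
        trace = make_trace(grid(96), np.full(96, 5.0))
        assert detect_excursions(trace, targets) == []

    def test_rectangular_step_90min(self, targets):
        # 5.0 baseline, step to 6.5 lasting 90 min (7 samples)
        g = np.full(96, 5.0)
        g[40:47] = 6.5
        trace = make_trace(grid(96), g)
        exc = detect_excursions(trace, targets)
        assert len(exc) == 1
        assert exc[0].onset == MIDNIGHT + dt.timedelta(minutes=240 + 40 * 15)
        assert exc[0].sustained_minutes == 90
        assert exc[0].reference == 5.0
        assert exc[0].peak == 6.5

    def test_step_45min_too_short(self, targets):
        g = np.full(96, 5.0)
        g[40:44] = 6.5  # 45 min elevated
        trace = make_trace(grid(96), g)
        assert detect_excursions(trace, targets) == []

    def test_vertical_shift_invariance(self, targets):
        # glucose quantized to exact binary fractions so the relative
        # elevation predicate is unaffected by representation error
        rng = np.random.default_rng(7)
        for _ in range(20):
            raw = random_trace(rng, max_samples=80)
            trace = make_trace(raw.minutes(), np.round(raw.glucose * 4) / 4)
            shifted = make_trace(trace.minutes(), trace.glucose + 2.25)
            a = detect_excursions(trace, targets)
            b = detect_excursions(shifted, targets)
            assert [(e.onset, e.end) for e in a] == [(e.onset, e.end) for e in b]

    def test_no_two_excursions_overlap(self, targets):
        rng = np.random.default_rng(11)
        for _ in range(50):
            trace = random_trace(rng, max_samples=120)
            exc = detect_excursions(trace, targets)
            for a, b in zip(exc, exc[1:]):
                assert a.end < b.onset

    def test_abutting_stretches_merge(self, targets):
        # two qualifying plateaus with no full missing sample between them
        g = np.full(96, 5.0)
        g[20:25] = 6.2   # 60 min at +1.2
        g[25:30] = 7.0   # immediately continues higher
        trace = make_trace(grid(96), g)
        exc = detect_excursions(trace, targets)
        assert len(exc) == 1
        assert exc[0].peak == 7.0

    def test_gap_breaks_sustain(self, targets):
        # elevated 45 min, 45-min hole, elevated 45 min: neither qualifies
        minutes = np.concatenate([grid(30), grid(30, start=240 + 33 * 15)])
        g = np.full(60, 5.0)
        g[26:30] = 6.5
        g[30:34] = 6.5
        trace = make_trace(minutes, g)
        assert detect_excursions(trace, targets) == []

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_bruteforce_oracle(self, seed):
        from trescore.study_model import ProtocolTargets
        targets = ProtocolTargets(baseline_first=480.0, baseline_last=1260.0)
        trace = random_trace(np.random.default_rng(seed), max_samples=60)
        got = detect_excursions(trace, targets)
        want = brute_force_excursions(trace)
        assert_same_excursions(trace, got, want)


class TestDailyGlucoseEvents:
    def test_first_and_last_onsets(self, targets):
        g = np.full(96, 5.0)
        g[22:28] = 6.5   # onset 09:40-ish (index 22 -> 09:30)
        g[60:66] = 6.5   # evening excursion
        trace = make_trace(grid(96), g)
        exc = detect_excursions(trace, targets)
        events = daily_glucose_events(exc, trace, DAY)
        assert events.n_excursions == 2
        assert events.first_onset == exc[0].onset
        assert events.last_onset == exc[-1].onset
        assert events.coverage_fraction == 1.0
        assert not events.missing

    def test_no_excursions_full_coverage(self, targets):
        trace = make_trace(grid(96), np.full(96, 5.0))
        events = daily_glucose_events([], trace, DAY)
        assert events.first_onset is None and events.n_excursions == 0
        assert not events.missing

    def test_sensor_failure_day_flagged_missing(self, targets):
        trace = make_trace(grid(10), np.full(10, 5.0))  # 10 of 96 samples
        events = daily_glucose_events([], trace, DAY)
        assert events.coverage_fraction < 0.5
        assert events.missing


def test_exclude_sleep_onsets_wraps_midnight(targets):
    g = np.full(96, 5.0)
    g[8:14] = 6.5    # onset 06:00, inside 23:00-07:00 sleep
    g[40:47] = 6.5   # onset 14:00, waking hours
    trace = make_trace(grid(96), g)
    exc = detect_excursions(trace, targets)
    assert len(exc) == 2
    kept = exclude_sleep_onsets(exc, 1380.0, 420.0)
    assert len(kept) == 1
    assert kept[0].onset.hour == 14
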