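"""Respiration preprocessing, breath detection, pause extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apnoea_eeg.respiration import (
    BreathSeries,
    PauseEvent,
    detect_breaths,
    filter_isolated,
    find_pauses,
    max_ibi_in_window,
    preprocess_respiration,
    select_baseline_window,
)

FS = 25.0


def hp_gain_analytic(f, fc=0.5, order=2, passes=2):
    """Squared-on-filtfilt magnitude of an analytic Butterworth high-pass."""
    r = (f / fc) ** (2 * order)
    return (r / (1.0 + r)) ** (passes / 2.0)


class TestPreprocess:
    def test_constant_signal_zeroed(self):
        y = preprocess_respiration(np.full(3000, 5.0), FS)
        assert np.abs(y).max() < 1e-6

    def test_tone_matches_analytic_highpass(self):
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        y = preprocess_respiration(x, FS)
        interior = slice(int(10 * FS), int(110 * FS))
        measured = np.abs(y[interior]).max()
        expected = hp_gain_analytic(1.0)
        assert measured == pytest.approx(expected, rel=0.01)

    def test_spike_removed(self):
        t = np.arange(int(60 * FS)) / FS
        clean = np.sin(2 * np.pi * 1.0 * t)
        x = clean.copy()
        x[int(30 * FS)] += 100 * clean.std()
        y = preprocess_respiration(x, FS)
        y_ref = preprocess_respiration(clean, FS)
        near = slice(int(29 * FS), int(31 * FS))
        assert np.abs(y[near] - y_ref[near]).max() < 0.05

    def test_nonfinite_rejected(self):
        x = np.ones(1000)
        x[3] = np.nan
        with pytest.raises(ValueError):
            preprocess_respiration(x, FS)


class TestDetectBreaths:
    def test_sinusoid_breath_count_and_ibis(self):
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        b = detect_breaths(x, FS)
        assert abs(b.breath_times.size - 120) <= 1
        assert np.allclose(b.ibis, 1.0, atol=0.05)

    def test_zero_signal_no_breaths(self):
        b = detect_breaths(np.zeros(int(120 * FS)), FS)
        assert b.breath_times.size == 0

    def test_silenced_gap_yields_single_long_ibi(self):
        t = np.arange(int(300 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        gap = (t >= 140) & (t < 160)
        x[gap] = 0.0
        b = detect_breaths(x, FS)
        long_ibis = b.ibis[b.ibis > 15]
        assert long_ibis.size == 1
        assert long_ibis[0] == pytest.approx(20.0, abs=1.5)

    @pytest.mark.parametrize("scale", [0.01, 1.0, 250.0])
    def test_amplitude_scale_invariance(self, scale, rng):
        t = np.arange(int(200 * FS)) / FS
        x = np.sin(2 * np.pi * 0.8 * t) + 0.05 * rng.standard_normal(t.size)
        ref = detect_breaths(x, FS).breath_times
        scaled = detect_breaths(scale * x, FS).breath_times
        assert np.array_equal(ref, scaled)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_breaths(np.ones(100), FS)


class TestFindPauses:
    @pytest.mark.parametrize(
        "ibis, min_s, max_s, expected",
        [
            ([1, 1, 20, 1], 5, np.inf, [("apnoea", 20.0)]),
            ([1, 6, 1], 5, 15, [("short", 6.0)]),
            ([1, 1, 1, 1], 5, np.inf, []),
        ],
    )
    def test_pause_extraction(self, ibis, min_s, max_s, expected):
        bt = np.concatenate([[0.0], np.cumsum(ibis)])
        events = find_pauses(BreathSeries(bt), min_s, max_s)
        got = [(e.category, e.duration_s) for e in events]
        assert got == [(c, pytest.approx(d)) for c, d in expected]


def brute_force_isolated(events, all_pauses, before=60.0, after=90.0):
    flags = []
    for ev in events:
        lo, hi = ev.start_s - before, ev.end_s + after
        iso = True
        for o in all_pauses:
            if (o.start_s, o.end_s) == (ev.start_s, ev.end_s):
                continue
            if lo <= o.start_s <= hi or lo <= o.end_s <= hi:
                iso = False
        flags.append(iso)
    return flags


class TestFilterIsolated:
    def test_single_pause_is_isolated(self):
        ev = [PauseEvent(100.0, 110.0)]
        assert filter_isolated(ev, ev)[0].isolated is True

    def test_two_close_pauses_not_isolated(self):
        evs = [PauseEvent(100.0, 108.0), PauseEvent(138.0, 146.0)]
        out = filter_isolated(evs, evs)
        assert [e.isolated for e in out] == [False, False]

    def test_two_distant_pauses_isolated(self):
        evs = [PauseEvent(100.0, 108.0), PauseEvent(308.0, 316.0)]
        out = filter_isolated(evs, evs)
        assert [e.isolated for e in out] == [True, True]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_agrees_with_brute_force(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 15))
        starts = np.sort(r.uniform(0, 2000, n))
        events = [PauseEvent(float(s), float(s + r.uniform(5, 30))) for s in starts]
        out = filter_isolated(events, events)
        assert [e.isolated for e in out] == brute_force_isolated(events, events)


def oracle_baseline(breaths, event, win_s, offset_s, back_s=90.0):
    first = max(0.0, event.start_s - back_s)
    last = event.start_s - offset_s - win_s
    best, best_v = None, np.inf
    a = first
    while a <= last + 1e-12:
        v = max_ibi_in_window(breaths, a, a + win_s)
        if v < best_v:
            best_v, best = v, (a, a + win_s)
        a += 1.0
    return best if np.isfinite(best_v) else None


class TestBaselineWindow:
    def test_uniform_ibis_earliest_window(self):
        bt = np.arange(0.0, 200.0, 1.0)
        ev = PauseEvent(150.0, 170.0)
        w = select_baseline_window(BreathSeries(bt), ev)
        assert w[0] == pytest.approx(150.0 - 90.0)

    def test_long_ibi_avoided(self):
        # one 4-s IBI ending 40 s before onset, otherwise 1-s breathing
        bt = np.concatenate([np.arange(0.0, 106.0), np.arange(110.0, 200.0)])
        ev = PauseEvent(150.0, 170.0)
        w = select_baseline_window(BreathSeries(bt), ev)
        # the 4-s IBI spans [106, 110); the chosen 30-s window must avoid it
        assert not (w[0] < 110.0 and 106.0 < w[1])
        assert max_ibi_in_window(BreathSeries(bt), *w) == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_exhaustive_grid_oracle(self, seed):
        r = np.random.default_rng(seed)
        ibis = r.uniform(0.8, 3.5, 200)
        bt = np.cumsum(ibis)
        start = float(bt[-1] - 5.0)
        ev = PauseEvent(start, start + 8.0)
        got = select_baseline_window(BreathSeries(bt), ev, win_s=10.0, search_end_offset_s=5.0)
        want = oracle_baseline(BreathSeries(bt), ev, 10.0, 5.0)
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want)

    def test_insufficient_pre_event_data(self):
        bt = np.arange(0.0, 40.0, 1.0)
        ev = PauseEvent(20.0, 30.0)
        assert select_baseline_window(BreathSeries(bt), ev, 30.0, 15.0) is None
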