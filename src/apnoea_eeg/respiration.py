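"""Breathing-pause detection from respiration traces.

The chain implemented here is: high-pass + outlier cleaning of the raw
respiration signal, adaptive-threshold breath detection, inter-breath-interval
(IBI) extraction, pause identification (apnoea >= 15 s, short pause 5-15 s),
an isolation filter that discards pauses with other pauses in temporal
proximity, and per-event selection of a normal-breathing baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

APNOEA_MIN_S = 15.0
SHORT_MIN_S = 5.0

__all__ = [
    "BreathSeries",
    "PauseEvent",
    "preprocess_respiration",
    "detect_breaths",
    "find_pauses",
    "filter_isolated",
    "select_baseline_window",
]


@dataclass(frozen=True)
class BreathSeries:
    """Detected breath times (s from recording start) and their IBIs."""

    breath_times: np.ndarray
    source_channel: str = "thorax"

    def __post_init__(self):
        bt = np.asarray(self.breath_times, dtype=float)
        object.__setattr__(self, "breath_times", bt)
        if bt.size > 1 and not np.all(np.diff(bt) > 0):
            raise ValueError("breath_times must be strictly increasing")

    @property
    def ibis(self) -> np.ndarray:
        return np.diff(self.breath_times)


@dataclass
class PauseEvent:
    """One breathing cessation, bounded by the flanking detected breaths."""

    start_s: float
    end_s: float
    isolated: Optional[bool] = None
    baseline_window: Optional[tuple[float, float]] = None
    extra: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def category(self) -> str:
        return "apnoea" if self.duration_s >= APNOEA_MIN_S else "short"


def _butter_hp_sos(fs: float, fc: float = 0.5, order: int = 2):
    return signal.butter(order, fc, btype="highpass", fs=fs, output="sos")


def preprocess_respiration(
    x: np.ndarray,
    fs: float,
    hp_hz: float = 0.5,
    outlier_sd: float = 5.0,
    n_iter: int = 10,
) -> np.ndarray:
    """High-pass filter and iteratively remove amplitude outliers.

    The trace is high-pass filtered (zero-phase second-order Butterworth at
    ``hp_hz``); then, up to ``n_iter`` times, samples exceeding
    ``outlier_sd`` times the filtered signal's standard deviation are
    replaced by linear interpolation between their neighbours in the raw
    trace and the filter is re-applied. Repairing the raw trace (rather
    than the filtered one) removes the zero-phase filter's ring-down around
    impulsive artifacts along with the artifact itself.
    """
    x = np.asarray(x, dtype=float).copy()
    if fs <= 1:
        raise ValueError("fs must exceed 1 Hz")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    sos = _butter_hp_sos(fs, hp_hz)
    y = signal.sosfiltfilt(sos, x)
    idx = np.arange(x.size)
    for _ in range(n_iter):
        sd = y.std()
        if sd == 0:
            break
        bad = np.abs(y) > outlier_sd * sd
        if not bad.any():
            break
        if bad.all():
            raise ValueError("all samples flagged as outliers")
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
        y = signal.sosfiltfilt(sos, x)
    return y


def detect_breaths(
    x: np.ndarray,
    fs: float,
    k: float = 0.5,
    w: int = 120,
    refractory_s: float = 0.5,
    source_channel: str = "thorax",
) -> BreathSeries:
    """Detect breaths as upward crossings of an adaptive amplitude threshold.

    The threshold ahead of each candidate equals ``k`` times the standard
    deviation of the signal spanning the previous ``w`` detected breaths.
    Before enough breaths exist the threshold is seeded by the SD of the
    first 60 s of signal. Crossings closer than ``refractory_s`` are merged.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n / fs < 60.0:
        raise ValueError("trace too short for adaptive breath detection (< 60 s)")
    seed_sd = x[: int(60 * fs)].std()
    if seed_sd == 0:
        return BreathSeries(np.empty(0), source_channel)
    # prefix sums for O(1) windowed SD
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_sd(i0: int, i1: int) -> float:
        m = i1 - i0
        if m < 2:
            return 0.0
        mu = (c1[i1] - c1[i0]) / m
        var = (c2[i1] - c2[i0]) / m - mu * mu
        return float(np.sqrt(max(var, 0.0)))

    breaths_idx: list[int] = []
    thr = k * seed_sd
    refr = int(round(refractory_s * fs))
    i = 1
    chunk = 4096
    while i < n:
        j_end = min(n, i + chunk)
        seg = x[i:j_end]
        prev = x[i - 1 : j_end - 1]
        cross = np.nonzero((prev < thr) & (seg >= thr))[0]
        hit = -1
        for c in cross:
            idx = i + c
            if not breaths_idx or idx - breaths_idx[-1] >= refr:
                hit = idx
                break
        if hit < 0:
            i = j_end
            continue
        breaths_idx.append(hit)
        # update threshold from the span of the last w breaths
        nb = len(breaths_idx)
        i0 = breaths_idx[max(0, nb - w)]
        i1 = breaths_idx[-1] + 1
        if nb >= 10 and (i1 - i0) / fs >= 30.0:
            thr = k * seg_sd(i0, i1)
        else:
            thr = k * seed_sd
        i = hit + 1
    times = np.asarray(breaths_idx, dtype=float) / fs
    return BreathSeries(times, source_channel)


def find_pauses(
    breaths: BreathSeries,
    min_s: float = SHORT_MIN_S,
    max_s: float = np.inf,
) -> list[PauseEvent]:
    """One PauseEvent per IBI in [min_s, max_s)."""
    bt = breaths.breath_times
    out = []
    for t0, t1 in zip(bt[:-1], bt[1:]):
        d = t1 - t0
        if min_s <= d < max_s:
            out.append(PauseEvent(start_s=float(t0), end_s=float(t1)))
    return out


def filter_isolated(
    events: Sequence[PauseEvent],
    all_pauses_ge_5s: Sequence[PauseEvent],
    before_s: float = 60.0,
    after_s: float = 90.0,
) -> list[PauseEvent]:
    """Flag each event as isolated iff no *other* >=5 s pause starts or ends
    inside [start - before_s, end + after_s]."""
    out = []
    for ev in events:
        lo, hi = ev.start_s - before_s, ev.end_s + after_s
        iso = True
        for other in all_pauses_ge_5s:
            if other.start_s == ev.start_s and other.end_s == ev.end_s:
                continue
            if lo <= other.start_s <= hi or lo <= other.end_s <= hi:
                iso = False
                break
        out.append(replace(ev, isolated=iso))
    return out


def max_ibi_in_window(breaths: BreathSeries, a: float, b: float) -> float:
    """Maximum IBI overlapping the window [a, b); inf if none overlaps."""
    bt = breaths.breath_times
    if bt.size < 2:
        return np.inf
    t0, t1 = bt[:-1], bt[1:]
    mask = (t1 > a) & (t0 < b)
    if not mask.any():
        return np.inf
    return float((t1[mask] - t0[mask]).max())


def select_baseline_window(
    breaths: BreathSeries,
    event: PauseEvent,
    win_s: Optional[float] = None,
    search_end_offset_s: Optional[float] = None,
    search_back_s: float = 90.0,
) -> Optional[tuple[float, float]]:
    """Select the normal-breathing window preceding a pause.

    Among candidate windows of length ``win_s`` with starts on a 1-s grid in
    [start - search_back_s, start - search_end_offset_s - win_s], returns the
    window minimising the maximum IBI overlapping it (earliest on ties).
    Defaults follow the event category: 30 s / 15 s for apnoeas, 10 s / 5 s
    for short pauses. Returns ``None`` when there is insufficient pre-event
    data (caller excludes the event).
    """
    if win_s is None:
        win_s = 30.0 if event.category == "apnoea" else 10.0
    if search_end_offset_s is None:
        search_end_offset_s = 15.0 if event.category == "apnoea" else 5.0
    first = max(0.0, event.start_s - search_back_s)
    last = event.start_s - search_end_offset_s - win_s
    if last < first:
        return None
    starts = first + np.arange(int(np.floor(last - first)) + 1, dtype=float)
    best = None
    best_val = np.inf
    for a in starts:
        v = max_ibi_in_window(breaths, a, a + win_s)
        if v < best_val:
            best_val = v
            best = (float(a), float(a + win_s))
    if best is None or not np.isfinite(best_val):
        return None
    return best
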