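"""Heart-rate and SpO2 cleaning and per-event change outcomes.

HR samples outside 40-230 bpm and SpO2 above 100% are marked missing (not
interpolated). Pulse-oximeters used at the cot side truncate SpO2 at 60%, so
readings of exactly 60 are kept but flagged as possibly truncated. The
per-event outcome is the minimum over [-5, +60] s relative to the pause end
minus the mean over the event's normal-breathing baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HR_MIN, HR_MAX = 40.0, 230.0
SPO2_MAX = 100.0
SPO2_FLOOR = 60.0
EVENT_WINDOW_S = (-5.0, 60.0)  # relative to pause end
MIN_COVERAGE = 0.5


@dataclass
class VitalsChange:
    hr_change: float
    spo2_change: float
    hr_valid: bool
    spo2_valid: bool
    floor_hit: bool


def clean_vitals(hr: np.ndarray, spo2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mask physiologically impossible samples as NaN.

    Returns (hr_clean, spo2_clean, floor_mask) where floor_mask marks SpO2
    samples sitting exactly on the 60% truncation floor.
    """
    hr = np.asarray(hr, dtype=float).copy()
    spo2 = np.asarray(spo2, dtype=float).copy()
    hr[(hr < HR_MIN) | (hr > HR_MAX)] = np.nan
    spo2[spo2 > SPO2_MAX] = np.nan
    floor = spo2 == SPO2_FLOOR
    return hr, spo2, floor


def _window_slice(n: int, fs: float, a_s: float, b_s: float) -> slice:
    i0 = max(0, int(round(a_s * fs)))
    i1 = min(n, int(round(b_s * fs)))
    return slice(i0, i1)


def event_change(
    series: np.ndarray,
    fs: float,
    event_end_s: float,
    baseline_window: tuple[float, float],
) -> tuple[float, bool, bool]:
    """min over [end-5, end+60] s minus mean over the baseline window.

    Returns (change, valid, floor_possible-placeholder). ``valid`` is False
    when either window has < 50% non-missing samples or leaves the series.
    Missing samples are excluded from the min/mean rather than interpolated.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    ev = _window_slice(n, fs, event_end_s + EVENT_WINDOW_S[0], event_end_s + EVENT_WINDOW_S[1])
    bl = _window_slice(n, fs, baseline_window[0], baseline_window[1])
    ev_seg, bl_seg = series[ev], series[bl]
    n_ev_expect = int(round((EVENT_WINDOW_S[1] - EVENT_WINDOW_S[0]) * fs))
    n_bl_expect = int(round((baseline_window[1] - baseline_window[0]) * fs))
    ok = (
        ev_seg.size >= max(1, n_ev_expect // 2)
        and bl_seg.size >= max(1, n_bl_expect // 2)
        and np.isfinite(ev_seg).mean() >= MIN_COVERAGE
        and np.isfinite(bl_seg).mean() >= MIN_COVERAGE
    )
    if not ok:
        return np.nan, False, False
    change = float(np.nanmin(ev_seg) - np.nanmean(bl_seg))
    floor_hit = bool(np.nanmin(ev_seg) == SPO2_FLOOR)
    return change, True, floor_hit


def vitals_changes(
    hr: np.ndarray,
    spo2: np.ndarray,
    fs: float,
    event_end_s: float,
    baseline_window: tuple[float, float],
) -> VitalsChange:
    """Cleaned per-event HR and SpO2 changes for one pause."""
    hr_c, spo2_c, _ = clean_vitals(hr, spo2)
    hr_change, hr_valid, _ = event_change(hr_c, fs, event_end_s, baseline_window)
    spo2_change, spo2_valid, floor_hit = event_change(spo2_c, fs, event_end_s, baseline_window)
    return VitalsChange(hr_change, spo2_change, hr_valid, spo2_valid, floor_hit)
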