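"""Time-frequency EEG amplitude via iterative narrowband Hilbert envelopes.

EEG is band-pass filtered 0.1-30 Hz, epoched around breathing-pause events,
amplitude-screened at +/-500 µV per channel, and transformed to a log10
amplitude stack: for each centre frequency 1.5...29.5 Hz (1-Hz steps) the
signal is band-passed +/-1 Hz, the analytic signal is taken via the Hilbert
transform, and its modulus gives the instantaneous amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)

CHANNELS_10_20 = ["Fp1", "Fp2", "C3", "Cz", "C4", "T3", "T4", "O1", "O2"]
CENTRE_FREQS = np.arange(1.5, 30.0, 1.0)  # 1.5, 2.5, ..., 29.5 Hz
LOG_FLOOR = 1e-6  # µV; keeps log10 finite on silent stretches
EDGE_DISCARD_S = 2.0  # Hilbert/filter settling excluded from statistics

# event-locked epoch extents, seconds relative to pause start
EPOCH_WINDOWS = {"apnoea": (-90.0, 150.0), "short": (-90.0, 90.0)}
# half-width of the statistical segments around lock points
SEGMENT_HALF_S = {"apnoea": 15.0, "short": 5.0}


@dataclass
class TFAEpoch:
    """log10 amplitude over time x frequency x channel plus axes metadata."""

    amplitude: np.ndarray  # (n_times, n_freqs, n_channels)
    times: np.ndarray  # s relative to lock point
    freqs: np.ndarray
    channels: list[str]
    lock: str = "start"


def bandpass_eeg(eeg: np.ndarray, fs: float, lo: float = 0.1, hi: float = 30.0) -> np.ndarray:
    """Zero-phase second-order Butterworth band-pass, per channel (axis 0 = time)."""
    eeg = np.asarray(eeg, dtype=float)
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if not np.all(np.isfinite(eeg)):
        raise ValueError("input contains non-finite samples")
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, eeg, axis=0)


def epoch_eeg(
    eeg: np.ndarray,
    fs: float,
    lock_times_s: Sequence[float],
    window: tuple[float, float],
) -> tuple[list[np.ndarray], list[int]]:
    """Cut fixed-length epochs around lock times.

    Returns (epochs, kept_indices); events whose window exceeds the recording
    are dropped with a log entry.
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    if eeg.shape[0] < eeg.shape[1]:  # accept (ch, time) or (time, ch)
        eeg = eeg.T
    n = eeg.shape[0]
    nw0, nw1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    epochs, kept = [], []
    for i, t in enumerate(lock_times_s):
        c = int(round(t * fs))
        if c + nw0 < 0 or c + nw1 > n:
            log.info("event %d at %.1f s dropped: window outside recording", i, t)
            continue
        epochs.append(eeg[c + nw0 : c + nw1])
        kept.append(i)
    return epochs, kept


def reject_epochs(epochs: Sequence[np.ndarray], limit_uv: float = 500.0) -> np.ndarray:
    """Channel-wise amplitude screen.

    Returns a keep mask of shape (n_epochs, n_channels): a channel-epoch is
    excluded if any sample exceeds +/-limit_uv.
    """
    if len(epochs) == 0:
        return np.zeros((0, 0), dtype=bool)
    masks = [np.max(np.abs(ep), axis=0) <= limit_uv for ep in epochs]
    return np.vstack(masks)


def tfa(
    epoch: np.ndarray,
    fs: float,
    centre_freqs: np.ndarray = CENTRE_FREQS,
    half_bw: float = 1.0,
    floor: float = LOG_FLOOR,
) -> np.ndarray:
    """log10 Hilbert-envelope amplitude per narrow band.

    ``epoch`` is (n_times,) or (n_times, n_channels); output is
    (n_times, n_freqs, n_channels). Each band uses a zero-phase second-order
    Butterworth band-pass at [f - half_bw, f + half_bw].
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[0] == 1:
        epoch = epoch.T
    n = epoch.shape[0]
    if n / fs < 10.0:
        raise ValueError("epoch shorter than 10 s: edge effects dominate")
    out = np.empty((n, len(centre_freqs), epoch.shape[1]))
    for fi, cf in enumerate(centre_freqs):
        sos = signal.butter(2, [cf - half_bw, cf + half_bw], btype="bandpass", fs=fs, output="sos")
        nb = signal.sosfiltfilt(sos, epoch, axis=0)
        amp = np.abs(signal.hilbert(nb, axis=0))
        out[:, fi, :] = np.log10(np.maximum(amp, floor))
    return out


def tfa_window(
    eeg: np.ndarray,
    fs: float,
    t0: float,
    t1: float,
    pad_s: float = 5.0,
    centre_freqs: np.ndarray = CENTRE_FREQS,
) -> Optional[np.ndarray]:
    """TFA of the recording interval [t0, t1), computed with ``pad_s`` of
    context on both sides to absorb filter/Hilbert edge effects.

    Returns (n_times, n_freqs, n_channels) or None when the padded interval
    leaves the recording.
    """
    pad_s = max(pad_s, EDGE_DISCARD_S)
    need = (t1 - t0) + 2 * pad_s
    if need < 10.0:  # grow the pad so the tfa() minimum-length rule holds
        pad_s += (10.0 - need) / 2.0
    epochs, kept = epoch_eeg(eeg, fs, [t0], (-pad_s, (t1 - t0) + pad_s))
    if not kept:
        return None
    a = tfa(epochs[0], fs, centre_freqs=centre_freqs)
    i0 = int(round(pad_s * fs))
    i1 = i0 + int(round((t1 - t0) * fs))
    return a[i0:i1]


def change_map(
    event_tfa: np.ndarray,
    baseline_tfa: np.ndarray,
    time_average_baseline: bool = False,
) -> np.ndarray:
    """Event log-amplitude minus matched normal-breathing log-amplitude.

    Sample-wise by default (segments must have equal shape); with
    ``time_average_baseline`` the baseline is first averaged over time.
    """
    if time_average_baseline:
        base = baseline_tfa.mean(axis=0, keepdims=True)
        return event_tfa - base
    if event_tfa.shape != baseline_tfa.shape:
        raise ValueError(
            f"shape mismatch: event {event_tfa.shape} vs baseline {baseline_tfa.shape}"
        )
    return event_tfa - baseline_tfa
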