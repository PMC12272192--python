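"""Synthetic multimodal neonatal recordings with known ground truth.

Every downstream stage of the pipeline has a recoverable target here:
quasi-periodic respiration whose envelope collapses during injected pauses,
1/f-like multichannel EEG whose instantaneous amplitude is multiplicatively
suppressed around each pause, heart-rate and SpO2 series with dips coupled
to pause severity (SpO2 floored at 60%, as cot-side monitors truncate it),
per-infant random variation of the suppression-bradycardia slope, and a
four-state sleep-label sequence in 30-s epochs.

The injected EEG suppression persists a few seconds past the pause end
(``post_suppression_s``), matching the observed lag of amplitude recovery
behind breathing resumption in real neonatal data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal

from .classifier import FEATURE_NAMES, extract_features
from .respiration import PauseEvent
from .stats import SLEEP_STATES

__all__ = [
    "SimConfig",
    "Recording",
    "GroundTruth",
    "simulate_recording",
    "simulate_cohort",
    "make_labelled_candidates",
    "simulate_lmm_dataset",
]

EEG_CHANNELS = ["Fp1", "Fp2", "C3", "Cz", "C4", "T3", "T4", "O1", "O2"]


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults emulate a term-corrected neonatal intensive-care recording:
    breathing around 0.75 Hz, pauses of 6-25 s separated by 150-250 s (so
    they are isolated), EEG background of ~30 µV RMS with 1/f spectral
    shape, baseline heart rate 120-170 bpm, SpO2 near 97%.
    """

    n_infants: int = 20
    duration_s: float = 1800.0
    fs_eeg: float = 250.0
    fs_resp: float = 25.0
    fs_vitals: float = 1.0
    breath_rate_hz: float = 0.75
    breath_jitter: float = 0.04  # fractional sd of instantaneous rate
    # explicit [(onset_s, duration_s), ...] or rate parameters for random placement
    pause_spec: Union[Sequence[tuple], dict, None] = None
    resp_residual_frac: float = 0.02  # chest-wall stillness during pauses
    suppression_log10: float = -0.2  # injected EEG amplitude change
    suppression_hr_slope: float = 0.0  # extra log10 units per bpm of HR change
    infant_slope_sd: float = 0.0  # between-infant sd of that slope
    post_suppression_s: float = 5.0  # suppression outlasts the pause end
    suppression_ramp_s: float = 1.0
    pre_onset_ramp_s: float = 5.0
    pre_onset_ramp: bool = False  # off by default so the null is clean
    hr_coupling: float = 1.5  # bpm dip per second of pause duration
    hr_lag_s: float = 10.0  # dip nadir relative to pause end
    hr_dip_sigma_s: float = 8.0
    spo2_coupling: float = 0.5  # percentage-point dip per second of duration
    spo2_lag_s: float = 25.0
    spo2_dip_sigma_s: float = 12.0
    hr_baseline_bpm: tuple = (120.0, 170.0)
    spo2_baseline_pct: float = 97.0
    eeg_rms_uv: float = 30.0
    noise_levels: dict = field(
        default_factory=lambda: {"resp": 0.05, "eeg_uv": 2.0, "hr_bpm": 2.0, "spo2_pct": 0.5}
    )
    pma_weeks_range: tuple = (36.0, 44.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("fs_eeg", "fs_resp", "fs_vitals", "breath_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.duration_s < 300:
            raise ValueError("duration_s must be >= 300 s")
        # normalise sequence-valued fields so YAML round trips compare equal
        self.hr_baseline_bpm = tuple(self.hr_baseline_bpm)
        self.pma_weeks_range = tuple(self.pma_weeks_range)
        if isinstance(self.pause_spec, dict):
            self.pause_spec = {k: tuple(v) for k, v in self.pause_spec.items()}
        if self.pause_spec is None:
            self.pause_spec = {"gap_s": (150.0, 250.0), "duration_s": (6.0, 25.0)}
        if isinstance(self.pause_spec, Sequence):
            ps = sorted(self.pause_spec)
            for (a0, d0), (a1, _) in zip(ps[:-1], ps[1:]):
                if a0 + d0 > a1:
                    raise ValueError("requested pauses overlap")
            for a, d in ps:
                if d >= self.duration_s or a + d > self.duration_s:
                    raise ValueError("pause exceeds recording")


@dataclass
class Recording:
    infant_id: str
    recording_id: str
    pma_weeks: float
    eeg: np.ndarray  # (n_samples, 9), µV
    eeg_channels: list
    fs_eeg: float
    resp: dict  # channel name -> (n_samples,) array
    fs_resp: float
    hr: np.ndarray
    spo2: np.ndarray
    fs_vitals: float
    sleep_labels: list  # one of SLEEP_STATES per 30-s epoch


@dataclass
class GroundTruth:
    true_pause_intervals: list  # [(start_s, end_s)] anchored to breath times
    severities: list  # pause duration, s
    injected_suppression: list  # log10 units per event
    hr_change_true: list  # bpm, negative
    spo2_change_true: list
    infant_slope: float
    breath_times: np.ndarray  # noiseless breath times
    sleep_labels: list


def _smooth_noise(rng, n, fs, cutoff_hz, sd):
    w = rng.standard_normal(n)
    if cutoff_hz >= fs / 2:
        return w * sd
    sos = signal.butter(2, cutoff_hz, fs=fs, output="sos")
    s = signal.sosfiltfilt(sos, w)
    s_sd = s.std()
    return s / s_sd * sd if s_sd > 0 else s


def _pink_noise(rng, n, fs, knee_hz=0.5):
    """1/f-power noise above ``knee_hz``, flat below; unit RMS."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, knee_hz))
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _breath_phase(rng, cfg: SimConfig):
    n = int(round(cfg.duration_s * cfg.fs_resp))
    jitter = _smooth_noise(rng, n, cfg.fs_resp, 0.05, cfg.breath_jitter)
    f_inst = cfg.breath_rate_hz * np.clip(1.0 + jitter, 0.3, 2.0)
    phase = 2 * np.pi * np.cumsum(f_inst) / cfg.fs_resp
    t = np.arange(n) / cfg.fs_resp
    k = np.arange(1, int(phase[-1] / (2 * np.pi)) + 1)
    breath_times = np.interp(2 * np.pi * k, phase, t)
    return t, phase, breath_times


def _place_pauses(rng, cfg: SimConfig, breath_times: np.ndarray):
    """Snap requested pauses to the noiseless breath grid.

    A pause is operationally an inter-breath gap, so the ground-truth
    interval runs from the last preserved breath to the first breath after
    the gap; the envelope gate sits strictly inside it.
    """
    if isinstance(cfg.pause_spec, dict):
        gaps = cfg.pause_spec.get("gap_s", (150.0, 250.0))
        durs = cfg.pause_spec.get("duration_s", (6.0, 25.0))
        requested = []
        t = 60.0 + rng.uniform(*gaps) / 2
        while True:
            d = rng.uniform(*durs)
            if t + d > cfg.duration_s - 120.0:
                break
            requested.append((t, d))
            t += d + rng.uniform(*gaps)
    else:
        requested = sorted((float(a), float(b)) for a, b in cfg.pause_spec)

    intervals = []
    period = 1.0 / cfg.breath_rate_hz
    for onset, dur in requested:
        i = np.searchsorted(breath_times, onset)
        if i >= breath_times.size:
            continue
        t_i = breath_times[i]
        j = np.searchsorted(breath_times, t_i + dur)
        if j >= breath_times.size or j <= i + 1:
            continue
        t_j = breath_times[j]
        if intervals and t_i <= intervals[-1][1]:
            raise ValueError("requested pauses overlap after snapping")
        intervals.append((float(t_i), float(t_j)))
    margin = 0.25 * period
    gates = [(a + margin, b - margin) for a, b in intervals]
    return intervals, gates


def _gate_envelope(t, gates, residual, ramp_s=0.3):
    env = np.ones_like(t)
    for g0, g1 in gates:
        rise = np.clip((t - g0) / ramp_s, 0, 1)
        fall = np.clip((g1 - t) / ramp_s, 0, 1)
        depth = np.minimum(rise, fall)  # 0 outside, 1 deep inside the gate
        env = np.minimum(env, 1.0 - (1.0 - residual) * depth)
    return env


def _log_gain(n: int, fs: float, intervals, suppressions, cfg: SimConfig):
    """log10 gain per sample; nonzero only near pauses, so computed locally."""
    g = np.zeros(n)
    r = cfg.suppression_ramp_s
    on_len = cfg.pre_onset_ramp_s if cfg.pre_onset_ramp else r
    for (a, b), s in zip(intervals, suppressions):
        lo = max(0, int((a - on_len - 1) * fs))
        hi = min(n, int((b + cfg.post_suppression_s + r + 1) * fs) + 1)
        t = np.arange(lo, hi) / fs
        if cfg.pre_onset_ramp:
            on = np.clip((t - (a - on_len)) / on_len, 0, 1)
        else:
            on = np.clip((t - a) / r, 0, 1)
        off = np.clip(((b + cfg.post_suppression_s + r) - t) / r, 0, 1)
        g[lo:hi] += s * np.minimum(on, off)
    return g


def _sleep_labels(rng, cfg: SimConfig, stay_p=0.85):
    n_ep = int(np.ceil(cfg.duration_s / 30.0))
    labels = [SLEEP_STATES[rng.integers(len(SLEEP_STATES))]]
    for _ in range(n_ep - 1):
        if rng.random() < stay_p:
            labels.append(labels[-1])
        else:
            others = [s for s in SLEEP_STATES if s != labels[-1]]
            labels.append(others[rng.integers(len(others))])
    return labels


def simulate_recording(
    cfg: SimConfig,
    infant_index: int = 0,
    modalities: tuple = ("resp", "eeg", "vitals"),
) -> tuple[Recording, GroundTruth]:
    """One infant session with full ground truth.

    Deterministic given (cfg.seed, infant_index); each modality draws from an
    independent stream, so omitting one from ``modalities`` (to save time in
    respiration-only experiments) leaves the others byte-identical.
    """
    rng = np.random.default_rng([cfg.seed, infant_index, 0])
    rng_resp = np.random.default_rng([cfg.seed, infant_index, 1])
    rng_eeg = np.random.default_rng([cfg.seed, infant_index, 2])
    rng_vit = np.random.default_rng([cfg.seed, infant_index, 3])
    amp_i = float(np.exp(rng.normal(0.0, 0.3)))
    slope_i = float(rng.normal(0.0, cfg.infant_slope_sd)) if cfg.infant_slope_sd > 0 else 0.0
    pma = float(rng.uniform(*cfg.pma_weeks_range))

    t_r, phase, breath_times = _breath_phase(rng, cfg)
    intervals, gates = _place_pauses(rng, cfg, breath_times)
    severities = [b - a for a, b in intervals]
    hr_true = [-cfg.hr_coupling * d for d in severities]
    spo2_true = [max(-cfg.spo2_coupling * d, 60.0 - cfg.spo2_baseline_pct) for d in severities]
    supp = [
        cfg.suppression_log10 + (cfg.suppression_hr_slope + slope_i) * dh
        for dh in hr_true
    ]

    # respiration channels: thorax / abdomen / nasal
    resp = {}
    if "resp" in modalities:
        env = _gate_envelope(t_r, gates, cfg.resp_residual_frac)
        for name, rel, dphi in (("thorax", 1.0, 0.0), ("abdomen", 0.8, 0.2), ("nasal", 0.6, 0.35)):
            carrier = np.sin(phase + dphi)
            noise = rng_resp.standard_normal(t_r.size) * cfg.noise_levels["resp"] * rel * amp_i
            resp[name] = amp_i * rel * env * carrier + noise

    # EEG: pink-noise background, multiplicative suppression during pauses
    n_eeg = int(round(cfg.duration_s * cfg.fs_eeg))
    eeg = np.empty((0, len(EEG_CHANNELS)))
    if "eeg" in modalities:
        gain = 10.0 ** _log_gain(n_eeg, cfg.fs_eeg, intervals, supp, cfg)
        eeg = np.empty((n_eeg, len(EEG_CHANNELS)))
        for ci in range(len(EEG_CHANNELS)):
            bg = _pink_noise(rng_eeg, n_eeg, cfg.fs_eeg) * cfg.eeg_rms_uv
            eeg[:, ci] = bg * gain + rng_eeg.standard_normal(n_eeg) * cfg.noise_levels["eeg_uv"]

    # vitals
    n_v = int(round(cfg.duration_s * cfg.fs_vitals))
    hr = np.empty(0)
    spo2 = np.empty(0)
    if "vitals" in modalities:
        t_v = np.arange(n_v) / cfg.fs_vitals
        hr_base = rng_vit.uniform(*cfg.hr_baseline_bpm)
        hr = (
            hr_base
            + _smooth_noise(rng_vit, n_v, cfg.fs_vitals, 0.01, 3.0)
            + rng_vit.standard_normal(n_v) * cfg.noise_levels["hr_bpm"]
        )
        spo2 = cfg.spo2_baseline_pct + rng_vit.standard_normal(n_v) * cfg.noise_levels["spo2_pct"]
        for (a, b), dh, ds in zip(intervals, hr_true, spo2_true):
            hr += dh * np.exp(-0.5 * ((t_v - (b + cfg.hr_lag_s)) / cfg.hr_dip_sigma_s) ** 2)
            spo2 += ds * np.exp(-0.5 * ((t_v - (b + cfg.spo2_lag_s)) / cfg.spo2_dip_sigma_s) ** 2)
        spo2 = np.clip(spo2, 60.0, None)

    labels = _sleep_labels(rng, cfg)
    rec = Recording(
        infant_id=f"inf{infant_index:03d}",
        recording_id=f"rec{infant_index:03d}",
        pma_weeks=pma,
        eeg=eeg,
        eeg_channels=list(EEG_CHANNELS),
        fs_eeg=cfg.fs_eeg,
        resp=resp,
        fs_resp=cfg.fs_resp,
        hr=hr,
        spo2=spo2,
        fs_vitals=cfg.fs_vitals,
        sleep_labels=labels,
    )
    gt = GroundTruth(
        true_pause_intervals=intervals,
        severities=severities,
        injected_suppression=supp,
        hr_change_true=hr_true,
        spo2_change_true=spo2_true,
        infant_slope=slope_i,
        breath_times=breath_times,
        sleep_labels=labels,
    )
    return rec, gt


def simulate_cohort(cfg: SimConfig, modalities: tuple = ("resp", "eeg", "vitals")):
    """Generator over ``cfg.n_infants`` (Recording, GroundTruth) pairs."""
    for i in range(cfg.n_infants):
        yield simulate_recording(cfg, infant_index=i, modalities=modalities)


def make_labelled_candidates(
    cfg: SimConfig,
    n_true: int = 100,
    n_false: int = 100,
    trace_s: float = 60.0,
    shallow_frac: tuple = (0.2, 0.4),
) -> pd.DataFrame:
    """Labelled candidate pauses for classifier training/testing.

    True candidates are genuine cessations (envelope collapses to the
    residual fraction); false candidates are shallow breathing, with the
    envelope reduced only to 20-40% of normal. Each candidate is a short
    standalone thoracic trace; the six features are extracted exactly as in
    the analysis path.
    """
    if n_true < 2 or n_false < 2:
        raise ValueError("need at least 2 candidates per class")
    rng = np.random.default_rng([cfg.seed, 977])
    rows = []
    labels = [True] * n_true + [False] * n_false
    for idx, lab in enumerate(labels):
        infant = idx % cfg.n_infants
        amp = float(np.exp(rng.normal(0.0, 0.3)))
        n = int(round(trace_s * cfg.fs_resp))
        t = np.arange(n) / cfg.fs_resp
        f = cfg.breath_rate_hz * (1 + rng.normal(0, cfg.breath_jitter))
        dur = rng.uniform(5.0, 15.0)
        g0 = trace_s / 2 - dur / 2
        residual = cfg.resp_residual_frac if lab else rng.uniform(*shallow_frac)
        env = _gate_envelope(t, [(g0, g0 + dur)], residual)
        x = amp * env * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        x += rng.standard_normal(n) * cfg.noise_levels["resp"] * amp
        ev = PauseEvent(start_s=g0, end_s=g0 + dur)
        feats = extract_features(x, cfg.fs_resp, ev, recording_sd=float(x.std()))
        row = {f_: getattr(feats, f_) for f_ in FEATURE_NAMES}
        row["label"] = lab
        row["infant_id"] = f"inf{infant:03d}"
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_lmm_dataset(
    n_infants: int = 60,
    events_per_infant: int = 20,
    beta0: float = -0.15,
    beta1: float = 0.001,
    slope_sd: float = 0.0005,
    intercept_sd: float = 0.02,
    resid_sd: float = 0.05,
    x_sd: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabular draw from the random-intercept + random-slope model used to
    validate the association fits (response ``eeg_change``, covariate ``x``)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_infants):
        u0 = rng.normal(0.0, intercept_sd)
        u1 = rng.normal(0.0, slope_sd)
        x = rng.normal(0.0, x_sd, events_per_infant)
        y = beta0 + u0 + (beta1 + u1) * x + rng.normal(0.0, resid_sd, events_per_infant)
        for xv, yv in zip(x, y):
            rows.append({"eeg_change": yv, "x": xv, "infant_id": f"inf{i:03d}"})
    return pd.DataFrame(rows)


def config_dict(cfg: SimConfig) -> dict:
    """Plain-dict echo of a SimConfig (for YAML round-tripping)."""
    d = asdict(cfg)
    if isinstance(d["pause_spec"], tuple):
        d["pause_spec"] = list(d["pause_spec"])
    return d
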