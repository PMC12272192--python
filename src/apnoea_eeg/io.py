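"""File-based interchange: EDF for EEG, tidy CSV for everything else."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .edf import write_edf
from .simulate import GroundTruth, Recording, SimConfig, config_dict


def write_recording(rec: Recording, gt: GroundTruth, out_dir) -> None:
    """EEG to EDF; respiration/vitals to tidy CSV (time_s, value); ground
    truth, sleep labels, and the config echo alongside."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edf(
        out / f"{rec.recording_id}_eeg.edf",
        rec.eeg,
        rec.fs_eeg,
        rec.eeg_channels,
        patient_id=rec.infant_id,
        recording_id=rec.recording_id,
    )
    t_r = np.arange(next(iter(rec.resp.values())).size) / rec.fs_resp
    for name, x in rec.resp.items():
        pd.DataFrame({"time_s": t_r, "value": x}).to_csv(
            out / f"{rec.recording_id}_resp_{name}.csv", index=False, float_format="%.6g"
        )
    t_v = np.arange(rec.hr.size) / rec.fs_vitals
    pd.DataFrame({"time_s": t_v, "hr_bpm": rec.hr, "spo2_pct": rec.spo2}).to_csv(
        out / f"{rec.recording_id}_vitals.csv", index=False, float_format="%.6g"
    )
    pd.DataFrame(
        {
            "start_s": [a for a, _ in gt.true_pause_intervals],
            "end_s": [b for _, b in gt.true_pause_intervals],
            "severity_s": gt.severities,
            "injected_suppression_log10": gt.injected_suppression,
            "hr_change_true_bpm": gt.hr_change_true,
            "spo2_change_true_pct": gt.spo2_change_true,
        }
    ).to_csv(out / f"{rec.recording_id}_truth.csv", index=False, float_format="%.6g")
    pd.DataFrame(
        {"epoch_start_s": 30.0 * np.arange(len(rec.sleep_labels)), "state": rec.sleep_labels}
    ).to_csv(out / f"{rec.recording_id}_sleep.csv", index=False, float_format="%.6g")


def write_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config_dict(cfg), f, sort_keys=True)


def read_config(path) -> SimConfig:
    with open(path) as f:
        d = yaml.safe_load(f)
    if isinstance(d.get("pause_spec"), list):
        d["pause_spec"] = [tuple(p) for p in d["pause_spec"]]
    return SimConfig(**d)


def read_respiration_csv(path) -> tuple[np.ndarray, float]:
    """(signal, fs) from a tidy (time_s, value) CSV with uniform sampling."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples")
    fs = 1.0 / np.median(np.diff(t))
    return df["value"].to_numpy(dtype=float), float(fs)


def read_eeg_edf(path) -> tuple[np.ndarray, float, list]:
    """(eeg (time, ch) in µV, fs, channel names) via mne's EDF reader."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads volts
    return data.T, float(raw.info["sfreq"]), list(raw.ch_names)
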