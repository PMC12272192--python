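"""Minimal writer for plain EDF (European Data Format, 16-bit).

Only the subset needed to store multichannel EEG at a single sampling rate
is implemented: one data-record duration, per-channel physical scaling, no
annotations. Files written here are readable by standard EDF readers
(round-tripped against mne's reader in the test suite).
"""

from __future__ import annotations

from datetime import datetime

import numpy as np


def _pad(s: str, n: int) -> bytes:
    b = str(s).encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(
    path,
    signals: np.ndarray,
    fs: float,
    channel_names,
    physical_unit: str = "uV",
    patient_id: str = "X",
    recording_id: str = "X",
    start: datetime | None = None,
    record_duration_s: float = 1.0,
) -> None:
    """Write ``signals`` (n_samples, n_channels) to a plain EDF file.

    Physical min/max are taken per channel from the data (symmetric, with a
    small margin) and mapped onto the full 16-bit digital range.
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if x.shape[0] < x.shape[1]:
        x = x.T
    n_samp, n_ch = x.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length must match signal count")
    spr = int(round(fs * record_duration_s))  # samples per record per channel
    n_rec = n_samp // spr
    if n_rec == 0:
        raise ValueError("signal shorter than one data record")
    x = x[: n_rec * spr]

    phys_max = np.maximum(np.abs(x).max(axis=0) * 1.01, 1e-3)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    start = start or datetime(2000, 1, 1, 0, 0, 0)

    hdr = b""
    hdr += _pad("0", 8)
    hdr += _pad(patient_id, 80)
    hdr += _pad(recording_id, 80)
    hdr += _pad(start.strftime("%d.%m.%y"), 8)
    hdr += _pad(start.strftime("%H.%M.%S"), 8)
    hdr += _pad(str(256 * (1 + n_ch)), 8)
    hdr += _pad("", 44)
    hdr += _pad(str(n_rec), 8)
    hdr += _pad(f"{record_duration_s:g}", 8)
    hdr += _pad(str(n_ch), 4)

    def field(values, width):
        return b"".join(_pad(v, width) for v in values)

    hdr += field(channel_names, 16)  # label
    hdr += field([""] * n_ch, 80)  # transducer
    hdr += field([physical_unit] * n_ch, 8)
    hdr += field([f"{v:.6g}" for v in phys_min], 8)
    hdr += field([f"{v:.6g}" for v in phys_max], 8)
    hdr += field([str(dig_min)] * n_ch, 8)
    hdr += field([str(dig_max)] * n_ch, 8)
    hdr += field([""] * n_ch, 80)  # prefiltering
    hdr += field([str(spr)] * n_ch, 8)
    hdr += field([""] * n_ch, 32)  # reserved

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    dig = np.round((x - phys_min) * scale + dig_min).astype("<i2")
    # records are channel-blocked: rec0[ch0 spr samples, ch1 ...], rec1[...]
    blocks = dig.reshape(n_rec, spr, n_ch).transpose(0, 2, 1)
    with open(path, "wb") as f:
        f.write(hdr)
        f.write(blocks.tobytes())
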