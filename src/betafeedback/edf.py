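"""Recording, event-table and ground-truth file I/O.

Recordings go to plain EDF (16-bit, one signal per channel, per-channel
physical scaling); no EDF export library ships with the scientific stack
used here, so the writer implements the fixed-layout EDF header directly.
Reading goes through MNE's EDF reader, which also serves as an independent
cross-check of the writer in the test suite.  Events are a tab-separated
table and the ground truth a JSON sidecar.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EVENT_COLUMNS, Recording, validate_event_table
from .synth import GroundTruth

__all__ = ["write_edf", "read_edf", "write_events", "read_events",
           "write_ground_truth", "read_ground_truth"]

_MODALITY_BY_PREFIX = {
    "LFP": "lfp", "EEG": "eeg", "EMG": "emg", "ACC": "accel", "FORCE": "force",
}


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, rec: Recording, record_duration: float = 1.0) -> Path:
    """Write a Recording as EDF; the final partial record is zero-padded."""
    path = Path(path)
    spr = record_duration * rec.rate
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("record duration times sampling rate must be an integer")
    spr = int(round(spr))
    ns = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((ns, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    # the header stores physical limits as 8-char ascii; quantize against the
    # values actually written so the scaling stays exact on read-back
    pmin = np.floor(pmin * 1e3) / 1e3  # exact 8-char decimal representation
    pmax = np.ceil(pmax * 1e3) / 1e3
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _fixed("0", 8),
        _fixed("X X X X", 80),
        _fixed(f"Startdate X X X X montage:{rec.montage}", 80),
        _fixed(now.strftime("%d.%m.%y"), 8),
        _fixed(now.strftime("%H.%M.%S"), 8),
        _fixed(str(256 * (ns + 1)), 8),
        _fixed("", 44),
        _fixed(str(n_rec), 8),
        _fixed(f"{record_duration:g}", 8),
        _fixed(str(ns), 4),
    ])
    fields = [
        [_fixed(lab, 16) for lab in rec.labels],
        [_fixed("", 80)] * ns,                      # transducer
        [_fixed("au", 8)] * ns,                     # physical dimension
        [_fixed(f"{v:.3f}"[:8], 8) for v in pmin],
        [_fixed(f"{v:.3f}"[:8], 8) for v in pmax],
        [_fixed(str(dmin), 8)] * ns,
        [_fixed(str(dmax), 8)] * ns,
        [_fixed("", 80)] * ns,                      # prefiltering
        [_fixed(str(spr), 8)] * ns,
        [_fixed("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(b"".join(block))
        # records: per record, per signal, contiguous int16 samples
        interleaved = digital.reshape(ns, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(interleaved).tobytes())
    return path


def read_edf(path) -> Recording:
    """Read an EDF recording through MNE (independent of the writer)."""
    from mne.io import read_raw_edf

    raw = read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    labels = list(raw.ch_names)
    modality = [_MODALITY_BY_PREFIX.get(lab.split("_")[0].split("-")[0].upper(), "lfp")
                for lab in labels]
    with open(path, "rb") as fh:  # montage tag lives in the recording-id field
        fh.seek(88)
        recording_id = fh.read(80).decode("ascii", errors="replace")
    montage = "bipolar" if "montage:bipolar" in recording_id else "monopolar"
    return Recording(data, float(raw.info["sfreq"]), labels, modality, montage)


def write_events(path, events: pd.DataFrame) -> Path:
    path = Path(path)
    validate_event_table(events).to_csv(path, sep="\t", index=False)
    return path


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"condition": str, "kind": str})
    df["trial_id"] = df["trial_id"].astype(int)
    return validate_event_table(df[EVENT_COLUMNS])


def write_ground_truth(path, gt: GroundTruth) -> Path:
    path = Path(path)
    payload = {
        "trials": gt.trials.to_dict(orient="list"),
        "burst_intervals": [[list(map(float, iv)) for iv in trial] for trial in gt.burst_intervals],
        "all_burst_intervals": [list(map(float, iv)) for iv in gt.all_burst_intervals],
        "rest_burst_intervals": [list(map(float, iv)) for iv in gt.rest_burst_intervals],
        "coupling_psi_true": gt.coupling_psi_true,
        "block_order": gt.block_order,
    }
    path.write_text(json.dumps(payload))
    return path


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        trials=pd.DataFrame(payload["trials"]),
        burst_intervals=[[tuple(iv) for iv in trial] for trial in payload["burst_intervals"]],
        all_burst_intervals=[tuple(iv) for iv in payload["all_burst_intervals"]],
        rest_burst_intervals=[tuple(iv) for iv in payload["rest_burst_intervals"]],
        coupling_psi_true=payload["coupling_psi_true"],
        block_order=payload["block_order"],
    )
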