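"""Cohort persistence and real-data ingestion.

Synthetic cohorts are written as one FIF file per subject plus a
``participants.tsv`` (participant_id, label), a minimal BIDS-like layout. For
real data the loader also accepts EDF and EEGLAB ``.set`` containers, the
common interchange formats for clinical resting-state EEG; all reading goes
through :mod:`mne`. Signals are stored by mne in volts and by this package in
microvolts; the converters handle the factor.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .montage import CHANNELS_1020
from .recording import RawRecording

__all__ = ["save_cohort", "load_cohort", "read_recording", "normalize_channel_name"]

_UV_PER_V = 1e6

#: Optional montage aliases (modern name -> classic 10-20 name). Disabled by
#: default; pass ``aliases=TEMPORAL_ALIASES`` to the readers to enable.
TEMPORAL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def normalize_channel_name(name: str, aliases: dict | None = None) -> str:
    """Canonicalise an electrode label against the 19-channel montage."""
    clean = name.strip().replace("EEG ", "").split("-")[0].strip()
    by_lower = {ch.lower(): ch for ch in CHANNELS_1020}
    if aliases:
        for alias, target in aliases.items():
            by_lower.setdefault(alias.lower(), target)
    return by_lower.get(clean.lower(), clean)


def save_cohort(cohort, out_dir: str) -> pd.DataFrame:
    """Write one FIF per subject plus participants.tsv; returns the table."""
    import mne

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in cohort:
        info = mne.create_info(
            list(rec.channel_names), rec.sampling_rate, ch_types="eeg"
        )
        raw = mne.io.RawArray(rec.data / _UV_PER_V, info, verbose="error")
        fname = os.path.join(out_dir, f"{rec.subject_id}_eeg_raw.fif")
        raw.save(fname, overwrite=True, verbose="error")
        rows.append({"participant_id": rec.subject_id, "label": rec.label})
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(out_dir, "participants.tsv"), sep="\t", index=False)
    return table


def read_recording(path: str, subject_id: str, label: str,
                   aliases: dict | None = None) -> RawRecording:
    """Read one EEG container (FIF, EDF or EEGLAB .set) into a RawRecording."""
    import mne

    ext = os.path.splitext(path)[1].lower()
    if ext == ".fif":
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    elif ext == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif ext == ".set":
        raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG container: {path!r}")
    names = [normalize_channel_name(ch, aliases) for ch in raw.ch_names]
    keep = [i for i, ch in enumerate(names) if ch in CHANNELS_1020]
    if not keep:
        raise ValueError(f"no 10-20 montage channels found in {path!r}")
    data = raw.get_data()[keep] * _UV_PER_V
    return RawRecording(
        subject_id=subject_id,
        label=label,
        channel_names=tuple(names[i] for i in keep),
        sampling_rate=float(raw.info["sfreq"]),
        data=data,
    )


def load_cohort(in_dir: str, aliases: dict | None = None) -> list:
    """Load a cohort saved by :func:`save_cohort` or a BIDS-like folder.

    Expects ``participants.tsv`` with participant_id and label columns; finds
    each subject's file by prefix among .fif/.edf/.set entries.
    """
    table = pd.read_csv(os.path.join(in_dir, "participants.tsv"), sep="\t")
    files = sorted(os.listdir(in_dir))
    cohort = []
    for _, row in table.iterrows():
        sid, label = str(row["participant_id"]), str(row["label"])
        match = [f for f in files
                 if f.startswith(sid)
                 and os.path.splitext(f)[1].lower() in (".fif", ".edf", ".set")]
        if not match:
            raise FileNotFoundError(f"no EEG file for subject {sid!r} in {in_dir!r}")
        cohort.append(
            read_recording(os.path.join(in_dir, match[0]), sid, label, aliases)
        )
    return cohort
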