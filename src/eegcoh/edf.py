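"""Minimal European Data Format (EDF) I/O for synthetic cohorts.

Writing uses a small self-contained EDF encoder (16-bit samples, 1 s data
records, physical unit microvolts); reading goes through MNE's EDF reader.
Subject labels travel in a sidecar CSV (subject_id, group, sex).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .montage import MontageSpec
from .synthetic import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    text = f"{value}"[:width]
    return text.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a recording as EDF (truncated to whole seconds)."""
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.data.shape[1] // fs
    n_signals = recording.montage.n_channels
    data = recording.data[:, : n_records * fs]

    # symmetric physical range per file keeps the gain identical across channels
    phys_max = float(np.ceil(np.abs(data).max() + 1.0))
    phys_min = -phys_max
    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - phys_min) / gain).astype(np.int64) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field(recording.subject_id, 80),
            _field(f"Startdate 01-JAN-2000 {recording.montage.name}", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(256 * (1 + n_signals), 8),
            _field("", 44),
            _field(n_records, 8),
            _field(1, 8),
            _field(n_signals, 4),
        ]
    )
    labels = recording.montage.channel_names
    signal_header = b"".join(
        [
            b"".join(_field(f"EEG {c}", 16) for c in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_field("uV", 8) for _ in labels),
            b"".join(_field(f"{phys_min:.1f}", 8) for _ in labels),
            b"".join(_field(f"{phys_max:.1f}", 8) for _ in labels),
            b"".join(_field(_DIG_MIN, 8) for _ in labels),
            b"".join(_field(_DIG_MAX, 8) for _ in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_field(fs, 8) for _ in labels),
            b"".join(_field("", 32) for _ in labels),
        ]
    )
    # records interleave: per record, all samples of signal 0, then signal 1, ...
    records = digital.reshape(n_signals, n_records, fs).transpose(1, 0, 2)
    path.write_bytes(header + signal_header + records.tobytes())
    return path


def read_edf(
    path: str | Path,
    montage: MontageSpec | None = None,
    group: str | None = None,
) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = tuple(n.removeprefix("EEG ").strip() for n in raw.ch_names)
    if montage is None:
        montage = MontageSpec(f"file:{Path(path).stem}", names)
    else:
        if tuple(montage.channel_names) != names:
            raise ValueError("EDF channel labels do not match the given montage")
    data = raw.get_data() * 1e6  # MNE returns volts
    subject_id = Path(path).stem
    return Recording(subject_id, group, data, float(raw.info["sfreq"]), montage)


def write_labels(labels: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    labels.to_csv(path, index=False)
    return path


def read_labels(path: str | Path) -> pd.DataFrame:
    labels = pd.read_csv(path)
    missing = {"subject_id", "group"} - set(labels.columns)
    if missing:
        raise ValueError(f"labels file lacks columns: {sorted(missing)}")
    return labels
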