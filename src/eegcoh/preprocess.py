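"""Automatic preprocessing: artifact reduction, segmentation, sampling, splits.

The cleaning chain discards the first 10 s of each recording, notch-filters
the 50 Hz line, then band-passes 0.5-44 Hz.  All filters are applied
forward-backward (zero phase): 4th-order Butterworth high- and low-pass and
an IIR notch with quality factor 30.  Recordings are tiled into five
non-overlapping 30 s sections; class balance is restored by sampling three of
the five sections per control subject while cases contribute all five.  Every
train/test partition is made at the subject level so that sections of one
person never appear on both sides of a split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal

from .synthetic import Recording

MIN_RAW_DURATION_S = 160.0
MIN_CLEAN_DURATION_S = 150.0
SECTION_S = 30.0
N_SECTIONS = 5


class LeakageError(RuntimeError):
    """A subject appeared on both sides of a train/test partition."""


@dataclass
class Section:
    """One 30 s section of a cleaned recording."""

    subject_id: str
    group: str | None
    section_index: int
    data: np.ndarray
    fs: float


@dataclass(frozen=True)
class SplitPlan:
    """Subject-level train/test partition."""

    train_subjects: frozenset[str]
    test_subjects: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.train_subjects & self.test_subjects:
            raise LeakageError("train and test subject sets overlap")


def clean(
    recording: Recording,
    discard_s: float = 10.0,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    highpass_hz: float = 0.5,
    lowpass_hz: float = 44.0,
    order: int = 4,
) -> Recording:
    """Discard the initial transient and filter (notch, then band-pass)."""
    if recording.duration_s < MIN_RAW_DURATION_S:
        raise ValueError(
            f"recording of subject {recording.subject_id!r} is too short "
            f"({recording.duration_s:.1f} s < {MIN_RAW_DURATION_S:.0f} s)"
        )
    fs = recording.fs
    data = recording.data[:, int(round(discard_s * fs)):]

    b_notch, a_notch = signal.iirnotch(notch_hz, notch_q, fs=fs)
    data = signal.filtfilt(b_notch, a_notch, data, axis=1)
    sos_hp = signal.butter(order, highpass_hz, btype="highpass", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos_hp, data, axis=1)
    sos_lp = signal.butter(order, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos_lp, data, axis=1)

    return Recording(
        recording.subject_id, recording.group, data, fs, recording.montage
    )


def filter_response(
    freq_hz: float,
    fs: float,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    highpass_hz: float = 0.5,
    lowpass_hz: float = 44.0,
    order: int = 4,
) -> float:
    """Magnitude response of the full zero-phase cleaning chain at one frequency."""
    w = [freq_hz]
    b, a = signal.iirnotch(notch_hz, notch_q, fs=fs)
    _, h_notch = signal.freqz(b, a, worN=w, fs=fs)
    sos_hp = signal.butter(order, highpass_hz, btype="highpass", fs=fs, output="sos")
    _, h_hp = signal.sosfreqz(sos_hp, worN=w, fs=fs)
    sos_lp = signal.butter(order, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    _, h_lp = signal.sosfreqz(sos_lp, worN=w, fs=fs)
    # forward-backward application squares each magnitude response
    return float((np.abs(h_notch[0]) * np.abs(h_hp[0]) * np.abs(h_lp[0])) ** 2)


def segment(recording: Recording) -> list[Section]:
    """Tile the cleaned recording into five 30 s sections from the start."""
    if recording.duration_s < MIN_CLEAN_DURATION_S:
        raise ValueError(
            f"cleaned recording of subject {recording.subject_id!r} is too "
            f"short ({recording.duration_s:.1f} s < {MIN_CLEAN_DURATION_S:.0f} s)"
        )
    per_section = int(round(SECTION_S * recording.fs))
    return [
        Section(
            subject_id=recording.subject_id,
            group=recording.group,
            section_index=k,
            data=recording.data[:, k * per_section:(k + 1) * per_section].copy(),
            fs=recording.fs,
        )
        for k in range(N_SECTIONS)
    ]


def balanced_sample_indices(
    subject_ids: Sequence[str],
    groups: Mapping[str, str],
    seed: int,
    n_control_sections: int = 3,
) -> tuple[np.ndarray, dict[str, tuple[int, ...]]]:
    """Row indices of the class-balancing sample over section rows.

    ``subject_ids`` gives the subject of each row (sections in time order per
    subject).  Cases keep all their rows; each control contributes
    ``n_control_sections`` rows chosen uniformly without replacement.  Returns
    the selected row indices plus a per-subject audit of chosen section
    positions.
    """
    subject_ids = np.asarray(subject_ids)
    rng = np.random.default_rng(seed)
    chosen_rows: list[int] = []
    audit: dict[str, tuple[int, ...]] = {}
    for subject in sorted(set(subject_ids)):
        rows = np.flatnonzero(subject_ids == subject)
        if groups[subject] == "case":
            picked = np.arange(rows.size)
        else:
            picked = np.sort(
                rng.choice(rows.size, size=n_control_sections, replace=False)
            )
        chosen_rows.extend(rows[picked])
        audit[subject] = tuple(int(p) for p in picked)
    return np.sort(np.asarray(chosen_rows, dtype=int)), audit


def balanced_sample(
    sections: Iterable[Section], seed: int, n_control_sections: int = 3
) -> tuple[list[Section], dict[str, tuple[int, ...]]]:
    """Class-balancing sample over :class:`Section` objects (see indices form)."""
    sections = list(sections)
    groups = {s.subject_id: s.group for s in sections}
    rows, audit = balanced_sample_indices(
        [s.subject_id for s in sections], groups, seed, n_control_sections
    )
    return [sections[i] for i in rows], audit


def subject_split(
    groups: Mapping[str, str], test_fraction: float = 0.10, seed: int = 0
) -> SplitPlan:
    """Stratified subject-level train/test split with ceil-rounded test size."""
    by_group: dict[str, list[str]] = {}
    for subject, group in groups.items():
        by_group.setdefault(group, []).append(subject)
    if len(by_group) < 2 or any(len(v) < 2 for v in by_group.values()):
        raise ValueError("need at least 2 subjects in each of 2 groups to split")

    n_total = len(groups)
    n_test = math.ceil(test_fraction * n_total)
    # largest-remainder allocation of the test quota across groups
    quotas = {g: test_fraction * len(v) for g, v in by_group.items()}
    alloc = {g: math.floor(q) for g, q in quotas.items()}
    remainders = sorted(
        by_group, key=lambda g: (quotas[g] - alloc[g], g), reverse=True
    )
    i = 0
    while sum(alloc.values()) < n_test:
        alloc[remainders[i % len(remainders)]] += 1
        i += 1

    rng = np.random.default_rng(seed)
    test: set[str] = set()
    for group in sorted(by_group):
        members = sorted(by_group[group])
        picked = rng.choice(len(members), size=alloc[group], replace=False)
        test.update(members[k] for k in picked)
    train = set(groups) - test
    return SplitPlan(frozenset(train), frozenset(test), seed)


def assert_subject_disjoint(
    train_subjects: Iterable[str], test_subjects: Iterable[str]
) -> None:
    """Raise :class:`LeakageError` if the two subject sets overlap."""
    overlap = set(train_subjects) & set(test_subjects)
    if overlap:
        raise LeakageError(f"subjects on both sides of a split: {sorted(overlap)}")
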