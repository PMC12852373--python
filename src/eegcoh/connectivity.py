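"""Epoch-wise spectral coherence features.

Each 30 s section is cut into 1 s epochs; per epoch and channel a
Hann-windowed discrete Fourier transform gives single-taper spectra on a
1 Hz grid.  The magnitude coherence of a channel pair is

    C(w) = |sum_e Sxy_e(w)| / sqrt(sum_e Sxx_e(w) * sum_e Syy_e(w)),

i.e. cross- and auto-spectra are averaged over epochs before the magnitude
ratio is taken (averaging the per-epoch ratio would be identically 1 for
single-taper spectra).  Band features are arithmetic means of C(w) over the
integer-frequency bins of the five clinical bands; a 19-channel montage
yields 171 pairs x 5 bands = 855 features, ordered pair-major (lexicographic
over the canonical channel order, i < j) and band-minor (delta..gamma).

Band-edge convention: shared edges (4, 8, 12, 30 Hz) belong to the lower
bin's upper band, i.e. intervals are half-open [lo, hi) except the last band
which is closed [30, 40].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .montage import MontageSpec, channel_pairs
from .preprocess import Section


@dataclass(frozen=True)
class BandTable:
    """Ordered named frequency bands in Hz."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 1.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("beta", 12.0, 30.0),
        ("gamma", 30.0, 40.0),
    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    def masks(self, freqs: np.ndarray) -> dict[str, np.ndarray]:
        """Boolean bin masks per band; last band closed at its upper edge."""
        out: dict[str, np.ndarray] = {}
        for k, (name, lo, hi) in enumerate(self.bands):
            if k == len(self.bands) - 1:
                mask = (freqs >= lo) & (freqs <= hi)
            else:
                mask = (freqs >= lo) & (freqs < hi)
            if not mask.any():
                raise ValueError(f"band {name!r} is empty on the frequency grid")
            out[name] = mask
        return out


DEFAULT_BANDS = BandTable()


@dataclass
class FeatureVector:
    """Band-averaged coherence features of one section."""

    values: np.ndarray
    names: tuple[str, ...]
    subject_id: str
    group: str | None
    section_index: int


def epoch(section: Section, epoch_s: float = 1.0) -> np.ndarray:
    """Cut a section into non-overlapping epochs: (n_epochs, n_ch, n_samp)."""
    per_epoch = int(round(epoch_s * section.fs))
    n_epochs = section.data.shape[1] // per_epoch
    trimmed = section.data[:, : n_epochs * per_epoch]
    return np.moveaxis(
        trimmed.reshape(trimmed.shape[0], n_epochs, per_epoch), 1, 0
    )


def _epoch_spectra(epochs: np.ndarray) -> np.ndarray:
    window = hann(epochs.shape[-1], sym=False)
    return np.fft.rfft(epochs * window, axis=-1)


def coherence_matrix(epochs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs magnitude coherence from epoched data.

    Returns ``(C, freqs_index)`` with C of shape (n_ch, n_ch, n_bins); the
    frequency grid is ``rfftfreq`` of the epoch length (1 Hz bins for 1 s
    epochs).  Bins with a zero auto-spectrum are defined as 0 with a warning.
    """
    if epochs.shape[0] < 2:
        raise ValueError("coherence needs at least 2 epochs")
    spectra = _epoch_spectra(epochs)
    cross = np.einsum("eif,ejf->ijf", spectra, spectra.conj())
    auto = np.einsum("iif->if", cross).real
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    zero = denom == 0.0
    if zero.any():
        warnings.warn(
            "zero auto-spectrum encountered; coherence defined as 0 there",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(zero, 0.0, np.abs(cross) / np.where(zero, 1.0, denom))
    return np.clip(coherence, 0.0, 1.0), np.arange(spectra.shape[-1], dtype=float)


def coherence(epochs: np.ndarray, pair: tuple[int, int]) -> np.ndarray:
    """Magnitude coherence spectrum of one channel pair."""
    if epochs.shape[0] < 2:
        raise ValueError("coherence needs at least 2 epochs")
    i, j = pair
    spectra = _epoch_spectra(epochs[:, [i, j], :])
    cross = np.abs((spectra[:, 0, :] * spectra[:, 1, :].conj()).sum(axis=0))
    auto_i = (np.abs(spectra[:, 0, :]) ** 2).sum(axis=0)
    auto_j = (np.abs(spectra[:, 1, :]) ** 2).sum(axis=0)
    denom = np.sqrt(auto_i * auto_j)
    zero = denom == 0.0
    if zero.any():
        warnings.warn(
            "zero auto-spectrum encountered; coherence defined as 0 there",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.clip(np.where(zero, 0.0, cross / np.where(zero, 1.0, denom)), 0.0, 1.0)


def feature_names(
    montage: MontageSpec, bands: BandTable = DEFAULT_BANDS
) -> tuple[str, ...]:
    """Canonical ordered feature names like ``"Fz-Cz:gamma"``."""
    names = []
    for i, j in channel_pairs(montage.n_channels):
        for band in bands.names:
            names.append(
                f"{montage.channel_names[i]}-{montage.channel_names[j]}:{band}"
            )
    return tuple(names)


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Split ``"Fz-Cz:gamma"`` into (channel_a, channel_b, band)."""
    pair, band = name.rsplit(":", 1)
    a, b = pair.split("-", 1)
    return a, b, band


def band_features(
    coherence_all: np.ndarray,
    freqs: np.ndarray,
    montage: MontageSpec,
    bands: BandTable = DEFAULT_BANDS,
) -> np.ndarray:
    """Band-mean coherence per (pair, band), pair-major band-minor order."""
    masks = bands.masks(np.asarray(freqs, dtype=float))
    pairs = channel_pairs(montage.n_channels)
    values = np.empty(len(pairs) * len(bands.names))
    band_means = {
        name: coherence_all[:, :, mask].mean(axis=2) for name, mask in masks.items()
    }
    for p, (i, j) in enumerate(pairs):
        for b, name in enumerate(bands.names):
            values[p * len(bands.names) + b] = band_means[name][i, j]
    return values


def section_features(
    section: Section, montage: MontageSpec, bands: BandTable = DEFAULT_BANDS
) -> FeatureVector:
    """The full coherence feature vector of one 30 s section."""
    epochs = epoch(section)
    coh, freqs = coherence_matrix(epochs)
    # 1 s epochs at integer fs put bins exactly on integer frequencies
    freqs = np.fft.rfftfreq(epochs.shape[-1], 1.0 / section.fs)
    return FeatureVector(
        values=band_features(coh, freqs, montage, bands),
        names=feature_names(montage, bands),
        subject_id=section.subject_id,
        group=section.group,
        section_index=section.section_index,
    )


def feature_table(
    sections: list[Section],
    montage: MontageSpec,
    bands: BandTable = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Feature matrix over sections: metadata columns then named features."""
    vectors = [section_features(s, montage, bands) for s in sections]
    if not vectors:
        raise ValueError("no sections given")
    names = vectors[0].names
    data = pd.DataFrame(
        np.vstack([v.values for v in vectors]), columns=list(names)
    )
    meta = pd.DataFrame(
        {
            "subject_id": [v.subject_id for v in vectors],
            "group": [v.group for v in vectors],
            "section_index": [v.section_index for v in vectors],
        }
    )
    return pd.concat([meta, data], axis=1)


META_COLUMNS = ("subject_id", "group", "section_index", "sex")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a feature table."""
    return [c for c in table.columns if c not in META_COLUMNS]
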