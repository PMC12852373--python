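"""Synthetic resting-state EEG with analytically controlled pairwise coherence.

Two-group cohorts are generated so that every downstream stage — filtering,
segmentation, coherence features, feature selection, classification — can be
exercised and validated without clinical recordings.  The group difference is
a planted, band-limited elevation (or depression) of magnitude coherence on a
configurable set of sensor pairs, realised by linearly mixing independent
band-limited sources:  for two channels x = sqrt(v)*s + sqrt(w)*n1 and
y = sqrt(v)*s + sqrt(w)*n2 sharing a source s, the magnitude coherence in the
band is exactly v / (v + w), which gives a closed-form oracle for estimator
tests.

When planted pairs share channels (the default five-pair set has Cz in three
pairs), a target coherence cannot be forced on the listed pairs while keeping
all other pairs at zero: positive-definiteness of the spectral matrix forces
some coherence on graph-adjacent pairs (a triangle-inequality-like
constraint).  The generator therefore completes the pair graph to a full
correlation matrix by assigning each unlisted pair the product of targets
along the shortest path connecting it in the pair graph — the maximum-entropy
completion for tree/chordal graphs — which keeps the listed pairs exactly at
target.  The achieved matrix is exposed for inspection.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.sparse.csgraph import shortest_path

from .montage import MontageSpec

DEFAULT_EFFECT_PAIRS = (
    ("Fz", "Cz"), ("Pz", "P4"), ("Fz", "C3"), ("Cz", "P4"), ("Cz", "Pz"),
)


@dataclass
class CohortSpec:
    """Parameters of a two-group synthetic EEG cohort.

    Amplitudes are in microvolts.  ``coh_case`` / ``coh_control`` are the
    target magnitude coherences on ``effect_pairs`` within ``band``;
    ``coh_sd`` is the per-block state fluctuation SD in Fisher-z units
    (see ``subject_block_matrices``).
    """

    n_cases: int
    n_controls: int
    duration_s: float = 170.0
    fs: float = 500.0
    effect_pairs: tuple[tuple[str, str], ...] = DEFAULT_EFFECT_PAIRS
    band: tuple[float, float] = (30.0, 40.0)
    coh_case: float = 0.8
    coh_control: float = 0.3
    coh_sd: float = 0.3
    coh_subject_rho: float = 0.0
    coh_block_s: float = 30.0
    one_over_f_exponent: float = 1.0
    background_rms: float = 20.0
    alpha_rms: float = 10.0
    alpha_freq: float = 10.0
    line_freq: float = 50.0
    line_rms: float = 5.0
    blink_rate_per_min: float = 10.0
    blink_amplitude: float = 90.0
    band_margin_hz: float = 1.0
    female_fraction: float = 0.5
    montage: MontageSpec = field(default_factory=MontageSpec.ten_twenty_19)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coh_case", "coh_control"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.duration_s < 160.0:
            raise ValueError(
                "duration_s must be at least 160 s so preprocessing "
                "(10 s discard + five 30 s sections) is possible"
            )
        for a, b in self.effect_pairs:
            if a not in self.montage or b not in self.montage:
                raise ValueError(f"effect pair ({a}, {b}) not in montage")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class Recording:
    """One subject's multichannel EEG (microvolts, channels x samples)."""

    subject_id: str
    group: str | None
    data: np.ndarray
    fs: float
    montage: MontageSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.montage.n_channels:
            raise ValueError("data must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


def plant_coherence_variances(target_coh: float) -> tuple[float, float]:
    """Shared/noise variances realising a target magnitude coherence.

    For x = s + n1, y = s + n2 with shared variance ``v`` and independent
    noise variance ``w`` per channel, the magnitude coherence is v/(v+w).
    Returns (v, w) normalised so v + w = 1.
    """
    if not 0.0 <= target_coh <= 1.0:
        raise ValueError(f"target coherence must be in [0, 1], got {target_coh}")
    return float(target_coh), float(1.0 - target_coh)


def coherence_completion(
    n_channels: int, pair_indices: list[tuple[int, int]], target: float
) -> np.ndarray:
    """Complete planted pairwise coherences to a full correlation matrix.

    Listed pairs get exactly ``target``; unlisted pairs connected in the pair
    graph get ``target ** path_length`` (shortest path), disconnected pairs 0.
    The result is eigenvalue-clipped at zero as a numerical safeguard; for
    tree/chordal pair graphs the path-product completion is already PSD and
    the clip is a no-op.
    """
    adjacency = np.zeros((n_channels, n_channels))
    for i, j in pair_indices:
        adjacency[i, j] = adjacency[j, i] = 1.0
    dist = shortest_path(adjacency, unweighted=True)
    with np.errstate(invalid="ignore"):
        matrix = np.where(np.isinf(dist), 0.0, target ** dist)
    np.fill_diagonal(matrix, 1.0)
    eigenvalues, vectors = np.linalg.eigh(matrix)
    if eigenvalues.min() < 0.0:
        eigenvalues = np.clip(eigenvalues, 1e-10, None)
        matrix = (vectors * eigenvalues) @ vectors.T
        scale = np.sqrt(np.diag(matrix))
        matrix = matrix / np.outer(scale, scale)
    return matrix


def subject_seed_sequence(seed: int, subject_id: str) -> np.random.SeedSequence:
    """Per-subject seed derived from (cohort seed, subject id).

    Hash-based so a subject's data do not depend on generation order.
    """
    digest = hashlib.sha256(subject_id.encode()).digest()
    return np.random.SeedSequence(
        [int(seed) % (2**31), int.from_bytes(digest[:4], "little")]
    )


def _psd_repair(matrix: np.ndarray) -> np.ndarray:
    eigenvalues, vectors = np.linalg.eigh(matrix)
    if eigenvalues.min() < 1e-10:
        eigenvalues = np.clip(eigenvalues, 1e-10, None)
        matrix = (vectors * eigenvalues) @ vectors.T
        scale = np.sqrt(np.diag(matrix))
        matrix = matrix / np.outer(scale, scale)
    return matrix


JITTER_FLOOR = 0.05
JITTER_CEIL = 0.95


def state_jitter_location(
    target: float, sd: float, lo: float = JITTER_FLOOR, hi: float = JITTER_CEIL
) -> float:
    """Fisher-z location ``mu`` with ``E[clip(tanh(mu + sd*Z), lo, hi)] == target``.

    Coherence is bounded in [0, 1], so an additive normal fluctuation around
    a high target is physically impossible: clipping it truncates the upper
    tail and either biases the realised mean below the stated group target
    or, if the location is mean-corrected in coherence space, piles mass at
    the ceiling and collapses the within-group variability.  The fluctuation
    is therefore modelled in Fisher-z space (``arctanh``, the standard
    variance-stabilising transform for coherence): a constant z-space SD
    compresses smoothly near 1, giving strong-coupling groups a naturally
    tighter coherence spread without any hard ceiling.  The remaining
    transform-induced mean shift (Jensen) is removed by solving for the
    z-space location whose clipped-tanh mean equals the target (64-point
    Gauss-Hermite quadrature, Brent root find).  Targets outside (lo, hi)
    cannot be mean-preserved and are mapped through ``arctanh`` directly.
    """
    if sd <= 0 or not lo < target < hi:
        return float(np.arctanh(np.clip(target, -0.999999, 0.999999)))

    nodes, weights = np.polynomial.hermite.hermgauss(64)
    z = np.sqrt(2.0) * nodes
    w = weights / np.sqrt(np.pi)

    def clipped_tanh_mean(mu: float) -> float:
        return float(np.sum(w * np.clip(np.tanh(mu + sd * z), lo, hi)))

    z_lo = float(np.arctanh(lo))
    z_hi = float(np.arctanh(hi))
    return float(
        brentq(
            lambda mu: clipped_tanh_mean(mu) - target,
            z_lo - 8 * sd,
            z_hi + 8 * sd,
        )
    )


def subject_block_matrices(
    spec: CohortSpec, target: float, rng: np.random.Generator, n_blocks: int
) -> np.ndarray:
    """In-band coherence matrices per 30 s state block, shape (B, ch, ch).

    The adjacency-forced entries (pairs connected through the effect-pair
    graph but not listed) are taken from the completion at the *stronger* of
    the two group targets and are identical for both groups and all blocks,
    so they carry no group signal.  The listed pairs get the group target
    plus a Fisher-z-space jitter of SD ``coh_sd``: a fraction
    ``coh_subject_rho`` of its variance is a stable subject trait (drawn
    once per pair), the rest fluctuates independently between blocks,
    modelling the non-stationarity of resting-state coupling.  The jitter
    location is bias-corrected (``state_jitter_location``) so the per-block
    coherence mean equals the group target, and values are clipped to
    [0.05, 0.95]: the ceiling keeps jittered hub pairs geometrically
    compatible with the fixed spillover entries (two triangle edges near 1
    would force the third above them, making the eigenvalue repair rewrite
    the matrix); tanh makes that tail rare.
    """
    pair_idx = [
        (spec.montage.index(a), spec.montage.index(b)) for a, b in spec.effect_pairs
    ]
    reference = max(spec.coh_case, spec.coh_control)
    base = coherence_completion(spec.montage.n_channels, pair_idx, reference)
    trait = {pair: rng.normal() for pair in pair_idx}
    location = state_jitter_location(target, spec.coh_sd)
    matrices = np.empty((n_blocks, base.shape[0], base.shape[1]))
    for b in range(n_blocks):
        matrix = base.copy()
        for i, j in pair_idx:
            value = target
            if spec.coh_sd > 0:
                jitter = (
                    np.sqrt(spec.coh_subject_rho) * trait[(i, j)]
                    + np.sqrt(1.0 - spec.coh_subject_rho) * rng.normal()
                )
                value = float(
                    np.clip(
                        np.tanh(location + spec.coh_sd * jitter),
                        JITTER_FLOOR,
                        JITTER_CEIL,
                    )
                )
            matrix[i, j] = matrix[j, i] = value
        matrices[b] = _psd_repair(matrix)
    return matrices


def subject_coherence_matrix(
    spec: CohortSpec, target: float, rng: np.random.Generator
) -> np.ndarray:
    """A single jittered in-band coherence matrix (one state block)."""
    return subject_block_matrices(spec, target, rng, 1)[0]


def _expected_irfft_variance(amplitude: np.ndarray, n: int) -> float:
    # variance of irfft of amplitude * z with z complex standard normal
    # (real DC/Nyquist bins); used for analytic RMS normalisation
    interior = amplitude[1:-1] if n % 2 == 0 else amplitude[1:]
    edge = amplitude[-1] ** 2 if n % 2 == 0 else 0.0
    return float((amplitude[0] ** 2 + 4.0 * np.sum(interior**2) + edge) / n**2)


def generate_subject(
    spec: CohortSpec,
    group: str,
    subject_id: str,
    seed: np.random.SeedSequence | int | None = None,
) -> Recording:
    """Generate one subject's recording with the group's planted coherence.

    The background is 1/f-shaped noise; all spectral content inside the
    effect band comes from the coherence-controlled mixed component (same
    1/f shaping, so the composite spectrum is seamless), giving in-band
    magnitude coherence equal to the completion matrix exactly in
    expectation.  An alpha rhythm, a common-phase power-line sinusoid and
    raised-cosine blink transients on the frontal-polar channels are added
    on top.
    """
    if group not in ("case", "control"):
        raise ValueError(f"group must be 'case' or 'control', got {group!r}")
    if seed is None:
        seed = subject_seed_sequence(spec.seed, subject_id)
    rng = np.random.default_rng(seed)

    n = spec.n_samples
    n_ch = spec.montage.n_channels
    freqs = np.fft.rfftfreq(n, 1.0 / spec.fs)
    n_bins = freqs.size

    # 1/f amplitude shaping, flattened below 1 Hz (the high-pass removes it
    # anyway and flat low end keeps EDF physical ranges sane)
    amplitude = np.maximum(freqs, 1.0) ** (-spec.one_over_f_exponent / 2.0)
    amplitude[0] = 0.0
    amplitude *= spec.background_rms / np.sqrt(_expected_irfft_variance(amplitude, n))

    spectrum = rng.standard_normal((n_ch, n_bins)) + 1j * rng.standard_normal(
        (n_ch, n_bins)
    )
    spectrum[:, 0] = spectrum[:, 0].real
    if n % 2 == 0:
        spectrum[:, -1] = spectrum[:, -1].real

    target = spec.coh_case if group == "case" else spec.coh_control
    # the planted band is widened by the Hann main-lobe half-width of a 1 s
    # epoch (1 Hz) so the coherence seen by the epoch estimator is flat
    # across every analysis bin of the nominal band, edges included
    lo = spec.band[0] - spec.band_margin_hz
    hi = spec.band[1] + spec.band_margin_hz
    in_band = (freqs >= lo) & (freqs <= hi)
    spectrum *= amplitude

    # alpha rhythm: gaussian spectral bump, independent per channel
    if spec.alpha_rms > 0:
        bump = np.exp(-0.5 * ((freqs - spec.alpha_freq) / 1.0) ** 2)
        bump *= spec.alpha_rms / np.sqrt(_expected_irfft_variance(bump, n))
        alpha_spec = (
            rng.standard_normal((n_ch, n_bins))
            + 1j * rng.standard_normal((n_ch, n_bins))
        )
        alpha_spec[:, 0] = alpha_spec[:, 0].real
        if n % 2 == 0:
            alpha_spec[:, -1] = alpha_spec[:, -1].real
        spectrum += alpha_spec * bump

    # split off the in-band component and mix it blockwise in the time
    # domain: the mixing matrix (Cholesky of the block's coherence matrix)
    # is constant within each 30 s state block, so coherence is planted
    # per block while fluctuating between blocks
    narrow = np.zeros_like(spectrum)
    narrow[:, in_band] = spectrum[:, in_band]
    spectrum[:, in_band] = 0.0
    in_band_ts = np.fft.irfft(narrow, n=n, axis=1)
    data = np.fft.irfft(spectrum, n=n, axis=1)

    block_len = int(round(spec.coh_block_s * spec.fs))
    edges = list(range(0, n, block_len)) + [n]
    matrices = subject_block_matrices(spec, target, rng, len(edges) - 1)
    for b in range(len(edges) - 1):
        mixing = np.linalg.cholesky(matrices[b] + 1e-12 * np.eye(n_ch))
        sl = slice(edges[b], edges[b + 1])
        data[:, sl] += mixing @ in_band_ts[:, sl]

    t = np.arange(n) / spec.fs
    if spec.line_rms > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        data += spec.line_rms * np.sqrt(2.0) * np.sin(
            2.0 * np.pi * spec.line_freq * t + phase
        )

    if spec.blink_rate_per_min > 0:
        frontal = [c for c in ("Fp1", "Fp2") if c in spec.montage]
        n_blinks = rng.poisson(spec.blink_rate_per_min * spec.duration_s / 60.0)
        for _ in range(n_blinks):
            width = rng.uniform(0.3, 0.5)
            center = rng.uniform(width, spec.duration_s - width)
            mask = np.abs(t - center) < width / 2.0
            pulse = (
                spec.blink_amplitude
                * 0.5
                * (1.0 + np.cos(2.0 * np.pi * (t[mask] - center) / width))
            )
            for k, ch in enumerate(frontal):
                data[spec.montage.index(ch), mask] += pulse * (1.0 - 0.1 * k)

    return Recording(subject_id, group, data, spec.fs, spec.montage)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate the full cohort plus a subject-level label table.

    The label table has columns subject_id, group, sex; sex is assigned
    independently of group so it is a pure (non-confounded) covariate for
    subgroup analyses.
    """
    recordings: list[Recording] = []
    rows = []
    for group, count in (("case", spec.n_cases), ("control", spec.n_controls)):
        for k in range(count):
            subject_id = f"{group}{k:03d}"
            recordings.append(generate_subject(spec, group, subject_id))
            sex_rng = np.random.default_rng(
                subject_seed_sequence(spec.seed + 1, subject_id)
            )
            sex = "F" if sex_rng.uniform() < spec.female_fraction else "M"
            rows.append({"subject_id": subject_id, "group": group, "sex": sex})
    labels = pd.DataFrame(rows)
    if labels["subject_id"].duplicated().any():
        raise RuntimeError("duplicate subject ids generated")
    return recordings, labels
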