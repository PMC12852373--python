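import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegcoh.connectivity import coherence
from eegcoh.montage import MontageSpec
from eegcoh.synthetic import (
    CohortSpec,
    Recording,
    coherence_completion,
    generate_cohort,
    generate_subject,
    plant_coherence_variances,
    state_jitter_location,
    subject_block_matrices,
    subject_coherence_matrix,
    subject_seed_sequence,
)


def test_plant_variances_sum_to_one():
    v, w = plant_coherence_variances(0.8)
    assert v == pytest.approx(0.8)
    assert v + w == pytest.approx(1.0)
    with pytest.raises(ValueError):
        plant_coherence_variances(1.2)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(min_value=0.05, max_value=0.95))
def test_shared_source_mixing_realises_target_coherence(target):
    """x = sqrt(v) s + sqrt(w) n has coherence v/(v+w) with its partner."""
    v, w = plant_coherence_variances(target)
    rng = np.random.default_rng(17)
    n_epochs, n_samp = 120, 200
    s = rng.standard_normal((n_epochs, n_samp))
    x = np.sqrt(v) * s + np.sqrt(w) * rng.standard_normal((n_epochs, n_samp))
    y = np.sqrt(v) * s + np.sqrt(w) * rng.standard_normal((n_epochs, n_samp))
    epochs = np.stack([x, y], axis=1)
    spectrum = coherence(epochs, (0, 1))
    # average over interior bins; edges of the rFFT grid behave differently
    assert np.mean(spectrum[2:-2]) == pytest.approx(target, abs=0.05)


def test_completion_listed_exact_and_path_products():
    pairs = [(0, 1), (1, 2)]
    matrix = coherence_completion(5, pairs, 0.8)
    assert matrix[0, 1] == pytest.approx(0.8)
    assert matrix[1, 2] == pytest.approx(0.8)
    assert matrix[0, 2] == pytest.approx(0.64)  # distance-2 path product
    assert matrix[0, 3] == 0.0  # disconnected
    assert matrix[3, 4] == 0.0
    assert np.allclose(matrix, matrix.T)
    assert np.linalg.eigvalsh(matrix).min() >= -1e-10


def test_completion_default_graph_is_psd():
    montage = MontageSpec.ten_twenty_19()
    spec = CohortSpec(n_cases=1, n_controls=1)
    pair_idx = [
        (montage.index(a), montage.index(b)) for a, b in spec.effect_pairs
    ]
    for target in (0.3, 0.8):
        matrix = coherence_completion(19, pair_idx, target)
        assert np.linalg.eigvalsh(matrix).min() >= -1e-10


def test_spillover_entries_identical_across_groups_without_jitter():
    montage = MontageSpec.ten_twenty_19()
    spec = CohortSpec(n_cases=1, n_controls=1, coh_sd=0.0)
    pair_idx = {
        tuple(sorted((montage.index(a), montage.index(b))))
        for a, b in spec.effect_pairs
    }
    case = subject_coherence_matrix(spec, spec.coh_case, np.random.default_rng(0))
    ctrl = subject_coherence_matrix(
        spec, spec.coh_control, np.random.default_rng(1)
    )
    listed = np.zeros((19, 19), dtype=bool)
    for i, j in pair_idx:
        listed[i, j] = listed[j, i] = True
    assert np.allclose(case[~listed], ctrl[~listed], atol=1e-9)
    for i, j in pair_idx:
        assert case[i, j] == pytest.approx(0.8)
        assert ctrl[i, j] == pytest.approx(0.3)


def test_state_jitter_location_preserves_target_mean():
    """Fisher-z location is corrected so E[clip(tanh(mu + sd Z))] hits target."""
    rng = np.random.default_rng(7)
    z = rng.standard_normal(200_000)
    for target in (0.3, 0.5, 0.8):
        loc = state_jitter_location(target, 0.3)
        draws = np.clip(np.tanh(loc + 0.3 * z), 0.05, 0.95)
        assert draws.mean() == pytest.approx(target, abs=0.005)
    # tanh is concave above 0, so the corrected location exceeds arctanh(t)
    assert state_jitter_location(0.8, 0.3) > np.arctanh(0.8)
    # strong coupling fluctuates less in coherence units than weak coupling
    sd_case = np.tanh(state_jitter_location(0.8, 0.3) + 0.3 * z).std()
    sd_control = np.tanh(state_jitter_location(0.3, 0.3) + 0.3 * z).std()
    assert sd_case < sd_control
    # degenerate cases map straight through arctanh
    assert state_jitter_location(0.8, 0.0) == pytest.approx(np.arctanh(0.8))
    assert state_jitter_location(0.99, 0.3) == pytest.approx(np.arctanh(0.99))


def test_block_matrices_fluctuate_and_stay_psd():
    spec = CohortSpec(n_cases=1, n_controls=1)
    mats = subject_block_matrices(
        spec, 0.5, np.random.default_rng(3), n_blocks=6
    )
    assert mats.shape == (6, 19, 19)
    i, j = 4, 9  # Fz-Cz, a listed pair
    values = mats[:, i, j]
    assert values.std() > 0.01  # state fluctuation present
    for m in mats:
        assert np.linalg.eigvalsh(m).min() >= -1e-8
        assert np.allclose(np.diag(m), 1.0)


def test_generate_subject_shape_and_determinism():
    spec = CohortSpec(n_cases=1, n_controls=1, duration_s=160, fs=250, seed=5)
    a = generate_subject(spec, "case", "case000")
    b = generate_subject(spec, "case", "case000")
    c = generate_subject(spec, "case", "case001")
    assert a.data.shape == (19, 160 * 250)
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)
    assert np.isfinite(a.data).all()


def test_generate_subject_rms_scale():
    spec = CohortSpec(
        n_cases=1, n_controls=1, duration_s=160, fs=250, seed=5,
        alpha_rms=0.0, line_rms=0.0, blink_rate_per_min=0.0,
    )
    rec = generate_subject(spec, "control", "control000")
    rms = rec.data.std()
    # background_rms=20 uV plus the in-band component on top
    assert 15.0 < rms < 40.0


def test_generate_subject_rejects_unknown_group():
    spec = CohortSpec(n_cases=1, n_controls=1)
    with pytest.raises(ValueError, match="group"):
        generate_subject(spec, "patient", "p0")


def test_cohort_labels(small_cohort, small_spec):
    recordings, labels = small_cohort
    assert len(recordings) == small_spec.n_cases + small_spec.n_controls
    assert set(labels.columns) == {"subject_id", "group", "sex"}
    assert labels["group"].value_counts()["case"] == small_spec.n_cases
    assert set(labels["sex"]) <= {"F", "M"}
    assert labels["subject_id"].is_unique


def test_spec_validation():
    with pytest.raises(ValueError, match="coh_case"):
        CohortSpec(n_cases=1, n_controls=1, coh_case=1.5)
    with pytest.raises(ValueError, match="duration_s"):
        CohortSpec(n_cases=1, n_controls=1, duration_s=100)
    with pytest.raises(ValueError, match="effect pair"):
        CohortSpec(n_cases=1, n_controls=1, effect_pairs=(("Xz", "Cz"),))


def test_recording_validation(montage19):
    with pytest.raises(ValueError, match="n_channels"):
        Recording("s", "case", np.zeros((3, 10)), 250.0, montage19)
    bad = np.zeros((19, 10))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        Recording("s", "case", bad, 250.0, montage19)


def test_subject_seed_is_order_independent():
    a = subject_seed_sequence(7, "case003")
    b = subject_seed_sequence(7, "case003")
    c = subject_seed_sequence(7, "case004")
    assert a.entropy == b.entropy
    assert a.entropy != c.entropy
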