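import numpy as np
import pytest
from sklearn.metrics import (
    accuracy_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from eegcoh.evaluate import (
    brier_score,
    calibration,
    default_gamma_grid,
    evaluate,
    expected_calibration_error,
    fit_final,
    grid_search_gamma,
    permutation_test,
    subgroup_filter_table,
)
from eegcoh.preprocess import LeakageError
from tests.conftest import gaussian_table

FEATURES = [f"f{k}:gamma" for k in range(3)]


def test_fit_final_separable_and_calibrated():
    table = gaussian_table(8, 8, FEATURES, {"f0:gamma": 0.5}, noise_sd=0.03)
    X = table[FEATURES].to_numpy()
    y = table["group"].to_numpy()
    model, calibrated = fit_final(X, y)
    assert accuracy_score(y, model.predict(X)) == 1.0
    proba = calibrated.predict_proba(X)
    assert proba.shape == (len(y), 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    _, none = fit_final(X, y, calibrate=False)
    assert none is None


def test_fit_final_single_class_rejected():
    X = np.zeros((4, 2))
    with pytest.raises(ValueError, match="single class"):
        fit_final(X, np.array(["case"] * 4))


def test_evaluate_metrics_match_sklearn():
    rng = np.random.default_rng(0)
    table = gaussian_table(6, 6, FEATURES, {"f0:gamma": 0.25}, noise_sd=0.15, seed=1)
    train = table[table["subject_id"].str.endswith(("0", "1", "2", "3"))]
    test = table[~table.index.isin(train.index)]
    model, _ = fit_final(
        train[FEATURES].to_numpy(), train["group"].to_numpy(), calibrate=False
    )
    report = evaluate(
        model,
        test[FEATURES].to_numpy(),
        test["group"].to_numpy(),
        test_subjects=test["subject_id"].tolist(),
        train_subjects=train["subject_id"].tolist(),
    )
    y_true = test["group"].to_numpy()
    y_pred = model.predict(test[FEATURES].to_numpy())
    assert report.accuracy == pytest.approx(accuracy_score(y_true, y_pred), abs=1e-12)
    assert report.precision == pytest.approx(
        precision_score(y_true, y_pred, pos_label="case", zero_division=0), abs=1e-12
    )
    assert report.recall == pytest.approx(
        recall_score(y_true, y_pred, pos_label="case", zero_division=0), abs=1e-12
    )
    assert report.n_test_sections == len(test)
    cm = report.confusion
    assert cm["tp"] + cm["fp"] + cm["fn"] + cm["tn"] == len(test)


def test_evaluate_auc_oriented_toward_case():
    """A perfectly separating model must yield AUC 1, not 0."""
    table = gaussian_table(5, 5, FEATURES, {"f0:gamma": 0.5}, noise_sd=0.03, seed=2)
    train = table[~table["subject_id"].isin(["case000", "control000"])]
    test = table[table["subject_id"].isin(["case000", "control000"])]
    model, _ = fit_final(
        train[FEATURES].to_numpy(), train["group"].to_numpy(), calibrate=False
    )
    report = evaluate(
        model,
        test[FEATURES].to_numpy(),
        test["group"].to_numpy(),
        test_subjects=test["subject_id"].tolist(),
        train_subjects=train["subject_id"].tolist(),
    )
    scores = model.decision_function(test[FEATURES].to_numpy())
    classes = list(model.classes_)
    oriented = -scores if classes.index("case") == 0 else scores
    expected = roc_auc_score(
        (test["group"] == "case").astype(int).to_numpy(), oriented
    )
    assert report.auc == pytest.approx(expected, abs=1e-12)
    assert report.auc == pytest.approx(1.0)


def test_evaluate_single_class_test_auc_none():
    table = gaussian_table(4, 4, FEATURES, {"f0:gamma": 0.5}, noise_sd=0.03, seed=3)
    train = table[table["subject_id"] != "case000"]
    test = table[table["subject_id"] == "case000"]
    model, _ = fit_final(
        train[FEATURES].to_numpy(), train["group"].to_numpy(), calibrate=False
    )
    report = evaluate(
        model,
        test[FEATURES].to_numpy(),
        test["group"].to_numpy(),
        test_subjects=["case000"],
        train_subjects=train["subject_id"].tolist(),
    )
    assert report.auc is None


def test_evaluate_guards_against_leakage():
    table = gaussian_table(4, 4, FEATURES, {"f0:gamma": 0.5}, seed=4)
    model, _ = fit_final(
        table[FEATURES].to_numpy(), table["group"].to_numpy(), calibrate=False
    )
    with pytest.raises(LeakageError):
        evaluate(
            model,
            table[FEATURES].to_numpy(),
            table["group"].to_numpy(),
            test_subjects=["case000"],
            train_subjects=["case000", "case001"],
        )


def test_gamma_grid_search_ties_prefer_smaller():
    table = gaussian_table(6, 6, FEATURES, {"f0:gamma": 0.5}, noise_sd=0.02, seed=5)
    X = table[FEATURES].to_numpy()
    y = table["group"].to_numpy()
    subjects = table["subject_id"].to_numpy()
    # both widths separate this easy problem perfectly -> tie -> smaller
    best = grid_search_gamma(X, y, subjects, grid=[5.0, 1.0], k_folds=4, repeats=2)
    assert best == 1.0
    with pytest.raises(ValueError, match="empty"):
        grid_search_gamma(X, y, subjects, grid=[])


def test_default_gamma_grid_span():
    grid = default_gamma_grid()
    assert grid.size == 25
    assert grid[0] == pytest.approx(1e-4)
    assert grid[-1] == pytest.approx(30.0)
    assert np.all(np.diff(grid) > 0)


def test_permutation_p_bounds_and_signal():
    # enough test subjects and noise that only near-true labelings can
    # classify the held-out sections perfectly
    table = gaussian_table(12, 12, FEATURES, {"f0:gamma": 0.3}, noise_sd=0.08,
                           seed=6)
    test_subjects = {"case000", "case001", "case002",
                     "control000", "control001", "control002"}
    train = table[~table["subject_id"].isin(test_subjects)]
    test = table[table["subject_id"].isin(test_subjects)]
    B = 49
    p, null_mean, null_sd = permutation_test(
        train, test, FEATURES, observed_accuracy=1.0, B=B, seed=0
    )
    # real labels separate perfectly; permuted labels rarely can
    assert 1.0 / (B + 1) <= p <= 1.0
    assert p < 0.1
    assert 0.0 <= null_mean <= 1.0
    # an unattainably low observed score must give p = 1
    p_high, _, _ = permutation_test(
        train, test, FEATURES, observed_accuracy=0.0, B=B, seed=0
    )
    assert p_high == 1.0
    with pytest.raises(ValueError, match="B"):
        permutation_test(train, test, FEATURES, 1.0, B=0)


def test_permutation_rank_arithmetic():
    # with observed above every null score, p is exactly 1/(B+1)
    table = gaussian_table(6, 6, FEATURES, {"f0:gamma": 0.6}, noise_sd=0.02, seed=7)
    test_subjects = {"case000", "case001", "control000", "control001"}
    train = table[~table["subject_id"].isin(test_subjects)]
    test = table[table["subject_id"].isin(test_subjects)]
    B = 19
    p, _, _ = permutation_test(
        train, test, FEATURES, observed_accuracy=1.01, B=B, seed=1
    )
    assert p == pytest.approx(1.0 / (B + 1))


def test_brier_closed_form():
    assert brier_score([0.9, 0.2], [1, 0]) == pytest.approx((0.01 + 0.04) / 2)
    assert brier_score([1.0, 0.0], [1, 0]) == 0.0
    assert brier_score([0.0], [1]) == 1.0
    with pytest.raises(ValueError):
        brier_score([], [])


def test_ece_matches_naive_binning():
    rng = np.random.default_rng(8)
    probs = rng.uniform(0, 1, 200)
    outcomes = (rng.uniform(0, 1, 200) < probs).astype(float)
    n_bins = 10
    # naive reference implementation
    expected = 0.0
    edges = np.linspace(0, 1, n_bins + 1)
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        mask = (probs >= lo) & (probs < hi) if b < n_bins - 1 else (
            (probs >= lo) & (probs <= hi)
        )
        if mask.any():
            expected += (
                mask.sum() / probs.size
                * abs(probs[mask].mean() - outcomes[mask].mean())
            )
    assert expected_calibration_error(probs, outcomes, n_bins) == pytest.approx(
        expected, abs=1e-12
    )


def test_ece_perfect_and_worst_case():
    assert expected_calibration_error([0.05] * 10, [0] * 10) == pytest.approx(0.05)
    assert expected_calibration_error([1.0, 0.0], [0, 1]) == pytest.approx(1.0)
    brier, ece = calibration([0.9, 0.1], [1, 0])
    assert brier == pytest.approx(0.01)
    assert ece == pytest.approx(0.1)


def test_subgroup_filter():
    table = gaussian_table(4, 4, FEATURES, {}, seed=9)
    table["sex"] = np.where(table["subject_id"].str.endswith(("0", "1")), "F", "M")
    females = subgroup_filter_table(table, "sex", "F")
    assert set(females["sex"]) == {"F"}
    assert set(females["group"]) == {"case", "control"}
    with pytest.raises(ValueError, match="covariate"):
        subgroup_filter_table(table, "age", 40)
    table_one = table[table["group"] == "case"].copy()
    with pytest.raises(ValueError, match="two-class"):
        subgroup_filter_table(table_one, "sex", "F")
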