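"""Final classifier fitting, held-out evaluation, significance and calibration.

The final model is a z-scored radial-basis-function support-vector
classifier trained on the balanced training sections; its RBF width is
picked by a grid search scored with the same subject-level wrapper CV used
during feature selection.  Held-out evaluation is section-level over all
five sections of every test subject.  Significance comes from a label
permutation test: subject-level labels of the training cohort are shuffled
(sections inherit their subject's permuted label), the balanced training set
is rebuilt and the classifier refit, and the untouched test sections are
rescored; the p-value uses the add-one convention
p = (1 + #{null >= observed}) / (1 + B), so p >= 1/(B+1).

Probabilities for the calibration metrics come from a Platt-style sigmoid
mapping of the decision values, fit by internal 5-fold cross-validation on
the training data (the classifier itself outputs margins, not
probabilities).  Brier is the mean squared probability error; ECE is the
bin-weighted absolute gap between mean predicted probability and empirical
frequency over 10 equal-width bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .preprocess import assert_subject_disjoint, balanced_sample_indices
from .selection import DEFAULT_GAMMA, make_rbf_classifier, wrapper_cv_score

POSITIVE_LABEL = "case"


@dataclass
class EvalReport:
    """Section-level held-out performance with significance and calibration."""

    accuracy: float
    precision: float
    recall: float
    auc: float | None
    confusion: dict[str, int]
    n_test_sections: int
    gamma: float
    seed: int
    permutation_p: float | None = None
    permutation_null_mean: float | None = None
    permutation_null_sd: float | None = None
    brier: float | None = None
    ece: float | None = None
    subgroup_filter: str | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def grid_search_gamma(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: Sequence[str],
    grid: Sequence[float],
    seed: int = 0,
    k_folds: int = 10,
    repeats: int = 10,
    C: float = 1.0,
) -> float:
    """Gamma in ``grid`` maximising wrapper-CV accuracy; ties -> smaller gamma."""
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("empty gamma grid")
    best_gamma, best_mean = None, -np.inf
    for gamma in grid:
        mean, _, _ = wrapper_cv_score(
            X, y, subject_ids, k_folds=k_folds, repeats=repeats, seed=seed,
            gamma=gamma, C=C,
        )
        if mean > best_mean:
            best_gamma, best_mean = gamma, mean
    return best_gamma


def default_gamma_grid(n_points: int = 25) -> np.ndarray:
    """Log-spaced RBF-width grid over the search range 0.0001-30."""
    return np.geomspace(1e-4, 30.0, n_points)


def fit_final(
    X: np.ndarray,
    y: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    C: float = 1.0,
    calibrate: bool = True,
    standardize: bool = False,
) -> tuple[Pipeline, CalibratedClassifierCV | None]:
    """Fit the RBF-SVM on the full balanced training set.

    Coherence features live on [0, 1] already, so z-scoring is optional.
    Returns the fitted pipeline and, when requested, a sigmoid-calibrated
    companion for probability estimates.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")

    def build() -> Pipeline:
        scale = StandardScaler() if standardize else "passthrough"
        return Pipeline([("scale", scale), ("svc", make_rbf_classifier(gamma, C))])

    model = build()
    model.fit(X, y)
    calibrated = None
    if calibrate:
        calibrated = CalibratedClassifierCV(build(), method="sigmoid", cv=5)
        calibrated.fit(X, y)
    return model, calibrated


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, int]:
    pos = POSITIVE_LABEL
    tp = int(np.sum((y_pred == pos) & (y_true == pos)))
    fp = int(np.sum((y_pred == pos) & (y_true != pos)))
    fn = int(np.sum((y_pred != pos) & (y_true == pos)))
    tn = int(np.sum((y_pred != pos) & (y_true != pos)))
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def evaluate(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    test_subjects: Sequence[str],
    train_subjects: Sequence[str],
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
) -> EvalReport:
    """Section-level metrics on the held-out sections of the test subjects."""
    assert_subject_disjoint(train_subjects, test_subjects)
    y_test = np.asarray(y_test)
    y_pred = model.predict(X_test)
    cm = _confusion(y_test, y_pred)
    total = len(y_test)
    accuracy = (cm["tp"] + cm["tn"]) / total
    precision = cm["tp"] / (cm["tp"] + cm["fp"]) if cm["tp"] + cm["fp"] else 0.0
    recall = cm["tp"] / (cm["tp"] + cm["fn"]) if cm["tp"] + cm["fn"] else 0.0
    if len(np.unique(y_test)) < 2:
        auc = None
    else:
        scores = np.asarray(model.decision_function(X_test), dtype=float)
        # decision values are oriented toward classes_[1]; flip if needed so
        # larger score means "case"
        classes = list(getattr(model, "classes_", ["case", "control"]))
        if classes.index(POSITIVE_LABEL) == 0:
            scores = -scores
        auc = float(roc_auc_score((y_test == POSITIVE_LABEL).astype(int), scores))
    return EvalReport(
        accuracy=float(accuracy),
        precision=float(precision),
        recall=float(recall),
        auc=auc,
        confusion=cm,
        n_test_sections=total,
        gamma=gamma,
        seed=seed,
    )


def permutation_test(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    features: Sequence[str],
    observed_accuracy: float,
    gamma: float = DEFAULT_GAMMA,
    C: float = 1.0,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Subject-level label-permutation null of the test accuracy.

    ``train_table`` holds all five sections per training subject (balancing
    is re-applied per shuffle, since it depends on the permuted labels);
    ``test_table`` is scored against its true labels.  Feature selection
    stays frozen.  Returns (p, null mean, null SD).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    features = list(features)
    rng = np.random.default_rng(seed)

    train_subjects = sorted(train_table["subject_id"].unique())
    true_groups = (
        train_table.drop_duplicates("subject_id")
        .set_index("subject_id")["group"]
        .to_dict()
    )
    X_test = test_table[features].to_numpy()
    y_test = test_table["group"].to_numpy()
    subject_col = train_table["subject_id"].to_numpy()

    null_scores = np.empty(B)
    for b in range(B):
        permuted = rng.permutation([true_groups[s] for s in train_subjects])
        perm_groups = dict(zip(train_subjects, permuted))
        rows, _ = balanced_sample_indices(
            subject_col, perm_groups, seed=int(rng.integers(2**31))
        )
        X_train = train_table.iloc[rows][features].to_numpy()
        y_train = np.array([perm_groups[s] for s in subject_col[rows]])
        if len(np.unique(y_train)) < 2:
            null_scores[b] = np.mean(y_test == y_train[0])
            continue
        model, _ = fit_final(X_train, y_train, gamma=gamma, C=C, calibrate=False)
        null_scores[b] = np.mean(model.predict(X_test) == y_test)

    p = (1.0 + np.sum(null_scores >= observed_accuracy - 1e-12)) / (1.0 + B)
    return float(p), float(null_scores.mean()), float(null_scores.std(ddof=1))


def brier_score(probabilities: np.ndarray, outcomes: np.ndarray) -> float:
    """Mean squared difference between probabilities and binary outcomes."""
    probabilities = np.asarray(probabilities, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if probabilities.size == 0:
        raise ValueError("empty input")
    return float(np.mean((probabilities - outcomes) ** 2))


def expected_calibration_error(
    probabilities: np.ndarray, outcomes: np.ndarray, n_bins: int = 10
) -> float:
    """Bin-weighted |mean probability - empirical frequency| over equal-width bins."""
    probabilities = np.asarray(probabilities, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if probabilities.size == 0:
        raise ValueError("empty input")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = np.clip(np.digitize(probabilities, edges[1:-1]), 0, n_bins - 1)
    total = probabilities.size
    ece = 0.0
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            gap = abs(probabilities[mask].mean() - outcomes[mask].mean())
            ece += mask.sum() / total * gap
    return float(ece)


def calibration(
    probabilities: np.ndarray, outcomes: np.ndarray, n_bins: int = 10
) -> tuple[float, float]:
    """(Brier, ECE) of predicted case-probabilities against binary outcomes."""
    return (
        brier_score(probabilities, outcomes),
        expected_calibration_error(probabilities, outcomes, n_bins),
    )


def subgroup_filter_table(
    table: pd.DataFrame, column: str, value
) -> pd.DataFrame:
    """Restrict a feature table to subjects with ``column == value``."""
    if column not in table.columns:
        raise ValueError(f"covariate column {column!r} not in table")
    filtered = table[table[column] == value].reset_index(drop=True)
    if filtered.empty or filtered["group"].nunique() < 2:
        raise ValueError(
            f"subgroup {column}={value!r} leaves no two-class cohort"
        )
    return filtered


__all__ = [
    "EvalReport",
    "grid_search_gamma",
    "default_gamma_grid",
    "fit_final",
    "evaluate",
    "permutation_test",
    "brier_score",
    "expected_calibration_error",
    "calibration",
    "subgroup_filter_table",
]
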