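"""Cross-domain validation: montage down-selection, fold sweep, instance transfer.

A feature signature discovered on a 19-channel cohort is validated on a
cohort recorded with a 64-channel 10-10 cap: the 19 corresponding electrodes
are extracted (legacy T3/T4/T5/T6 names map to modern T7/T8/P7/P8), and the
target cohort is evaluated under stratified subject-level k-fold
cross-validation for every fold count k = 2..24, in two modes — a classifier
trained directly on the target training folds, and a TrAdaBoost
instance-transfer classifier that re-weights source-domain sections while
boosting on the target training folds.  With n target subjects, the average
number of training subjects at fold count k is n*(k-1)/k, so the sweep
doubles as a learning curve; an ordinary least-squares line of score against
training size summarises the trend.

TrAdaBoost (boosting for transfer learning): weights start uniform over
source + target samples; each round trains the weighted base learner and
measures the weighted error e_t on the target only.  Misclassified source
samples decay by the fixed factor beta = 1 / (1 + sqrt(2 ln n / N)); and
misclassified target samples are up-weighted by (e_t/(1-e_t))^-1.  The final
prediction is a vote over the last ceil(N/2) rounds weighted by
ln((1-e_t)/e_t).  Rounds with target error >= 1/2 stop the loop; zero error
is clamped to 1/(2m) to keep the vote weights finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.preprocessing import StandardScaler

from .montage import MontageSpec, TEN_TWENTY_19
from .preprocess import assert_subject_disjoint
from .selection import DEFAULT_GAMMA, make_rbf_classifier, stratified_subject_folds
from .synthetic import Recording


@dataclass
class TransferResult:
    """Per-fold-count scores for direct training and instance transfer."""

    fold_counts: list[int] = field(default_factory=list)
    avg_train_subjects: list[float] = field(default_factory=list)
    direct_scores: list[float] = field(default_factory=list)
    transfer_scores: list[float] = field(default_factory=list)
    direct_trend: tuple[float, float] | None = None  # (slope, intercept)
    transfer_trend: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "folds": self.fold_counts,
                "avg_train_subjects": self.avg_train_subjects,
                "transfer_score": self.transfer_scores,
                "direct_score": self.direct_scores,
            }
        )


def map_montage(recording: Recording) -> Recording:
    """Down-select a recording to the canonical 19-channel 10-20 montage.

    Channels are matched by name with legacy/modern equivalences resolved;
    all other channels are dropped and the canonical order is imposed.
    """
    missing = [c for c in TEN_TWENTY_19 if c not in recording.montage]
    if missing:
        raise ValueError(
            f"montage {recording.montage.name!r} lacks required electrodes: "
            f"{missing}"
        )
    rows = [recording.montage.index(c) for c in TEN_TWENTY_19]
    return Recording(
        recording.subject_id,
        recording.group,
        recording.data[rows],
        recording.fs,
        MontageSpec.ten_twenty_19(),
    )


class TrAdaBoostClassifier:
    """Instance-transfer boosting with a weighted base learner."""

    def __init__(
        self,
        base_estimator=None,
        n_rounds: int = 20,
        seed: int = 0,
        standardize: bool = False,
        learning_rate: float = 0.5,
    ):
        """Boosted instance transfer from a source to a target domain.

        ``learning_rate`` shrinks the target-side (AdaBoost) weight updates
        (``w /= beta_t ** learning_rate``): an unshrunk update can multiply a
        hard sample's weight by an order of magnitude in a single round,
        which destabilises strong base learners such as an RBF-SVM.  The
        source decay factor ``beta`` is the fixed constant of the transfer
        bound and is applied at full strength.
        """
        if n_rounds < 2:
            raise ValueError("n_rounds must be >= 2")
        if not 0.0 < learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")
        self.base_estimator = (
            base_estimator
            if base_estimator is not None
            else make_rbf_classifier(DEFAULT_GAMMA)
        )
        self.n_rounds = n_rounds
        self.seed = seed
        self.standardize = standardize
        self.learning_rate = learning_rate

    def fit(
        self,
        X_source: np.ndarray,
        y_source: np.ndarray,
        X_target: np.ndarray,
        y_target: np.ndarray,
    ) -> "TrAdaBoostClassifier":
        X_source = np.atleast_2d(np.asarray(X_source, dtype=float))
        X_target = np.atleast_2d(np.asarray(X_target, dtype=float))
        if X_source.shape[0] == 0:
            X = X_target
            X_source = np.empty((0, X_target.shape[1]))
        else:
            X = np.vstack([X_source, X_target])
        y = np.concatenate([np.asarray(y_source), np.asarray(y_target)])
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("TrAdaBoost requires exactly two classes")
        n = X_source.shape[0]
        m = X_target.shape[0]
        N = self.n_rounds

        self.scaler_ = StandardScaler().fit(X) if self.standardize else None
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X

        weights = np.ones(n + m) / (n + m)
        beta = 1.0 / (1.0 + sqrt(2.0 * log(n) / N)) if n > 0 else 1.0
        self.beta_ = beta
        self.rounds_: list[tuple[object, float]] = []  # (model, beta_t)
        self.weight_history_ = [weights.copy()]

        target_slice = slice(n, n + m)
        for _ in range(N):
            w = weights / weights.sum()
            model = clone(self.base_estimator)
            model.fit(Xs, y, sample_weight=w * (n + m))
            predictions = model.predict(Xs)
            mistakes = predictions != y

            w_target = w[target_slice]
            epsilon_t = float(
                np.sum(w_target * mistakes[target_slice]) / np.sum(w_target)
            )
            if epsilon_t >= 0.5:
                break
            epsilon_t = max(epsilon_t, 1.0 / (2.0 * m))
            beta_t = epsilon_t / (1.0 - epsilon_t)
            self.rounds_.append((model, beta_t))

            if n > 0:
                weights[:n] = np.where(
                    mistakes[:n], weights[:n] * beta, weights[:n]
                )
            weights[target_slice] = np.where(
                mistakes[target_slice],
                weights[target_slice] / beta_t**self.learning_rate,
                weights[target_slice],
            )
            self.weight_history_.append(weights.copy())

        if not self.rounds_:
            # degenerate start: keep the first learner with a nominal weight
            model = clone(self.base_estimator)
            model.fit(Xs, y, sample_weight=weights * (n + m))
            self.rounds_.append((model, 1.0 - 1e-6))
        self.n_source_ = n
        self.n_target_ = m
        return self

    def source_weight_share(self) -> float:
        """Final share of total weight mass held by source samples."""
        final = self.weight_history_[-1]
        return float(final[: self.n_source_].sum() / final.sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = np.atleast_2d(np.asarray(X, dtype=float))
        if self.scaler_ is not None:
            Xs = self.scaler_.transform(Xs)
        start = ceil(len(self.rounds_) / 2) - 1  # vote over rounds ceil(N/2)..N
        votes = np.zeros((Xs.shape[0],))
        for model, beta_t in self.rounds_[start:]:
            weight = log(1.0 / beta_t)
            votes += weight * np.where(
                model.predict(Xs) == self.classes_[1], 1.0, -1.0
            )
        return np.where(votes >= 0.0, self.classes_[1], self.classes_[0])


def _subject_matrix(
    table: pd.DataFrame, features: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = table[list(features)].to_numpy()
    y = table["group"].to_numpy()
    subjects = table["subject_id"].to_numpy()
    return X, y, subjects


def fold_sweep(
    target_table: pd.DataFrame,
    features: Sequence[str],
    source_table: pd.DataFrame | None = None,
    k_range: Sequence[int] = tuple(range(2, 25)),
    gamma: float = DEFAULT_GAMMA,
    C: float = 1.0,
    n_rounds: int = 20,
    seed: int = 0,
) -> TransferResult:
    """Stratified subject-level CV of the signature over fold counts 2..24.

    For each fold count, each held-out fold is scored by a classifier
    trained directly on the remaining target folds and — when a source
    table is given — by a TrAdaBoost classifier transferring the source
    sections onto those folds.
    """
    X_t, y_t, subj_t = _subject_matrix(target_table, features)
    groups = {s: g for s, g in zip(subj_t, y_t)}
    subjects = sorted(groups)
    per_class = min(
        sum(1 for s in subjects if groups[s] == g) for g in set(groups.values())
    )

    if source_table is not None:
        X_s, y_s, _ = _subject_matrix(source_table, features)
    result = TransferResult()
    rows_by_subject = {s: np.flatnonzero(subj_t == s) for s in subjects}

    for k in k_range:
        if k > per_class:
            import warnings

            warnings.warn(
                f"skipping k={k}: more folds than subjects per class",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        folds = stratified_subject_folds(subjects, groups, k, rng)
        direct_fold, transfer_fold = [], []
        for fold in folds:
            held = set(fold)
            train_subjects = [s for s in subjects if s not in held]
            assert_subject_disjoint(train_subjects, held)
            train_rows = np.concatenate([rows_by_subject[s] for s in train_subjects])
            test_rows = np.concatenate([rows_by_subject[s] for s in sorted(held)])

            direct = make_rbf_classifier(gamma, C)
            direct.fit(X_t[train_rows], y_t[train_rows])
            direct_fold.append(
                float(np.mean(direct.predict(X_t[test_rows]) == y_t[test_rows]))
            )
            if source_table is not None:
                booster = TrAdaBoostClassifier(
                    make_rbf_classifier(gamma, C), n_rounds=n_rounds, seed=seed
                )
                booster.fit(X_s, y_s, X_t[train_rows], y_t[train_rows])
                transfer_fold.append(
                    float(np.mean(booster.predict(X_t[test_rows]) == y_t[test_rows]))
                )

        n = len(subjects)
        result.fold_counts.append(int(k))
        result.avg_train_subjects.append(n * (k - 1) / k)
        result.direct_scores.append(float(np.mean(direct_fold)))
        result.transfer_scores.append(
            float(np.mean(transfer_fold)) if transfer_fold else float("nan")
        )

    result.direct_trend = trend_regression(
        result.direct_scores, result.avg_train_subjects
    )
    if source_table is not None:
        result.transfer_trend = trend_regression(
            result.transfer_scores, result.avg_train_subjects
        )
    return result


def trend_regression(
    scores: Sequence[float], train_sizes: Sequence[float]
) -> tuple[float, float]:
    """Ordinary least-squares line of score against training size.

    Returns (slope, intercept).
    """
    x = np.asarray(train_sizes, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("trend regression needs at least 2 points")
    if np.ptp(x) == 0.0:
        raise ValueError("training sizes are constant; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
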