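"""Sequential floating forward selection with an SVM-wrapper cross-validation.

Candidate feature subsets are scored by repeated subject-level k-fold
cross-validation of a radial-basis-function support-vector classifier: folds
partition subjects (never sections), stratified by group, and the score of a
subset is the mean section-level validation accuracy over all
``repeats x k_folds`` trials (10 x 10 = 100 by default).  Coherence
features already share the [0, 1] scale the default RBF width assumes, so
z-scoring is off by default; when enabled it uses training-fold statistics
only.

The floating search adds, at each step, the candidate whose wrapper score is
highest, then repeatedly removes a feature whenever the reduced subset beats
the best score previously recorded at that smaller size.  Exact accuracy
ties — unavoidable once a subset classifies every validation section
correctly — are broken by the subset's mean per-feature Fisher discriminant
ratio, and only then by the lower feature index.  The best subset ever seen
at each size 1..max_k is recorded in a :class:`SelectionTrace`.
The wrapper's RBF width ``gamma`` is held fixed during the search (the value
found by the grid search of the evaluation stage); nested re-tuning inside
every candidate evaluation is an extension point, not the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectivity import parse_feature_name
from .preprocess import assert_subject_disjoint

DEFAULT_GAMMA = 5.1053
DEFAULT_ROI = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")


@dataclass
class SelectionTrace:
    """SFFS trajectory: best recorded subset and wrapper score per size."""

    sizes: list[int] = field(default_factory=list)
    subsets: list[tuple[int, ...]] = field(default_factory=list)
    means: list[float] = field(default_factory=list)
    sds: list[float] = field(default_factory=list)
    cis: list[tuple[float, float]] = field(default_factory=list)
    n_trials: int = 100
    seed: int = 0
    chosen_k: int | None = None

    def record(self, subset: tuple[int, ...], mean: float, sd: float,
               ci: tuple[float, float]) -> None:
        size = len(subset)
        if size in self.sizes:
            i = self.sizes.index(size)
            self.subsets[i], self.means[i], self.sds[i], self.cis[i] = (
                subset, mean, sd, ci
            )
        else:
            self.sizes.append(size)
            self.subsets.append(subset)
            self.means.append(mean)
            self.sds.append(sd)
            self.cis.append(ci)

    def best_at(self, size: int) -> tuple[tuple[int, ...], float]:
        i = self.sizes.index(size)
        return self.subsets[i], self.means[i]

    def to_json(self, path: str | Path, feature_names: Sequence[str] | None = None
                ) -> Path:
        payload = {
            "seed": self.seed,
            "n_trials": self.n_trials,
            "chosen_k": self.chosen_k,
            "trace": [
                {
                    "size": s,
                    "features": list(sub),
                    "feature_names": (
                        [feature_names[i] for i in sub] if feature_names else None
                    ),
                    "cv_mean": m,
                    "cv_sd": sd,
                    "cv_ci95": list(ci),
                }
                for s, sub, m, sd, ci in zip(
                    self.sizes, self.subsets, self.means, self.sds, self.cis
                )
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path


def make_rbf_classifier(gamma: float = DEFAULT_GAMMA, C: float = 1.0) -> SVC:
    """The pipeline's wrapper/final classifier."""
    return SVC(kernel="rbf", gamma=gamma, C=C)


def stratified_subject_folds(
    subjects: Sequence[str],
    groups: dict[str, str],
    k_folds: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Deal shuffled subjects of each group round-robin into ``k_folds`` folds."""
    folds: list[list[str]] = [[] for _ in range(k_folds)]
    offset = 0
    for group in sorted(set(groups.values())):
        members = sorted(s for s in subjects if groups[s] == group)
        order = rng.permutation(len(members))
        for pos, idx in enumerate(order):
            folds[(offset + pos) % k_folds].append(members[idx])
        offset += len(members)
    return folds


def wrapper_cv_score(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: Sequence[str],
    k_folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    gamma: float = DEFAULT_GAMMA,
    C: float = 1.0,
    standardize: bool = False,
    make_classifier: Callable[[], object] | None = None,
) -> tuple[float, float, tuple[float, float]]:
    """Repeated subject-level k-fold CV accuracy of an RBF-SVM on X.

    Returns (mean, sd, 95% CI) over the ``repeats * k_folds`` trial
    accuracies, each the section-level accuracy on the held-out subjects.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subject_ids = np.asarray(subject_ids)
    groups = {}
    for s, label in zip(subject_ids, y):
        groups[s] = label
    unique_subjects = sorted(groups)
    if len(unique_subjects) < k_folds:
        raise ValueError(
            f"{len(unique_subjects)} subjects cannot fill {k_folds} folds"
        )

    if make_classifier is None:
        prototype = make_rbf_classifier(gamma=gamma, C=C)
        make_classifier = lambda: clone(prototype)  # noqa: E731

    rows_by_subject = {s: np.flatnonzero(subject_ids == s) for s in unique_subjects}
    scores = []
    for repeat in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, repeat]))
        folds = stratified_subject_folds(
            unique_subjects, {s: str(groups[s]) for s in unique_subjects},
            k_folds, rng,
        )
        for fold in folds:
            val_subjects = set(fold)
            train_subjects = set(unique_subjects) - val_subjects
            assert_subject_disjoint(train_subjects, val_subjects)
            train_rows = np.concatenate(
                [rows_by_subject[s] for s in sorted(train_subjects)]
            )
            val_rows = np.concatenate(
                [rows_by_subject[s] for s in sorted(val_subjects)]
            )
            X_train, X_val = X[train_rows], X[val_rows]
            if standardize:
                scaler = StandardScaler().fit(X_train)
                X_train = scaler.transform(X_train)
                X_val = scaler.transform(X_val)
            model = make_classifier()
            model.fit(X_train, y[train_rows])
            scores.append(float(np.mean(model.predict(X_val) == y[val_rows])))

    scores = np.asarray(scores)
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    half = 1.96 * sd / np.sqrt(scores.size)
    return mean, sd, (mean - half, mean + half)


def sffs(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: Sequence[str],
    candidates: Sequence[int] | None = None,
    max_k: int = 20,
    floating: bool = True,
    k_folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    gamma: float = DEFAULT_GAMMA,
    C: float = 1.0,
) -> SelectionTrace:
    """Sequential (floating) forward selection over ``candidates``.

    Subsets are compared by wrapper CV accuracy first.  Exact accuracy ties
    are unavoidable once a subset classifies every validation section
    correctly and the accuracy criterion stops discriminating; they are
    broken by the subset's mean per-feature Fisher discriminant ratio
    ``(mean_1 - mean_2)^2 / (var_1 + var_2)`` — among equal-error subsets
    the one whose features carry more class separation is preferred (the
    classic hybrid filter-wrapper criterion) — and remaining ties toward
    the lower canonical feature index.  With ``floating=False`` the search
    reduces to plain sequential forward selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if candidates is None:
        candidates = list(range(X.shape[1]))
    candidates = sorted(int(c) for c in candidates)
    if not candidates:
        raise ValueError("no candidate features")
    max_k = min(max_k, len(candidates))

    labels = sorted(set(y))
    if len(labels) == 2:
        a, b = (y == labels[0]), (y == labels[1])
        gap = X[a].mean(axis=0) - X[b].mean(axis=0)
        spread = X[a].var(axis=0) + X[b].var(axis=0)
        fisher = gap**2 / np.maximum(spread, 1e-12)
    else:
        fisher = np.zeros(X.shape[1])

    cache: dict[tuple[int, ...], tuple] = {}

    def score(subset: tuple[int, ...]):
        if subset not in cache:
            stats = wrapper_cv_score(
                X[:, list(subset)], y, subject_ids,
                k_folds=k_folds, repeats=repeats, seed=seed, gamma=gamma, C=C,
            )
            cache[subset] = (*stats, float(fisher[list(subset)].mean()))
        return cache[subset]

    def better(stats, than) -> bool:
        if than is None:
            return True
        if abs(stats[0] - than[0]) > 1e-12:
            return stats[0] > than[0]
        return stats[3] > than[3] + 1e-12

    trace = SelectionTrace(n_trials=k_folds * repeats, seed=seed)
    recorded_stats: dict[int, tuple] = {}

    def record(subset: tuple[int, ...], stats) -> None:
        recorded_stats[len(subset)] = stats
        trace.record(subset, *stats[:3])

    current: list[int] = []
    while len(current) < max_k:
        best_feature, best_stats = None, None
        for feature in candidates:
            if feature in current:
                continue
            stats = score(tuple(sorted(current + [feature])))
            if better(stats, best_stats):
                best_feature, best_stats = feature, stats
        current.append(best_feature)
        current.sort()
        if better(best_stats, recorded_stats.get(len(current))):
            record(tuple(current), best_stats)

        while floating and len(current) > 2:
            best_removal, removal_stats = None, None
            for feature in current:
                reduced = tuple(f for f in current if f != feature)
                stats = score(reduced)
                if better(stats, removal_stats):
                    best_removal, removal_stats = feature, stats
            size = len(current) - 1
            if size in recorded_stats and better(
                removal_stats, recorded_stats[size]
            ):
                current.remove(best_removal)
                record(tuple(current), removal_stats)
            else:
                break

    trace.sizes, trace.subsets, trace.means, trace.sds, trace.cis = map(
        list,
        zip(*sorted(zip(trace.sizes, trace.subsets, trace.means, trace.sds,
                        trace.cis))),
    )
    return trace


def choose_k(trace: SelectionTrace, rule: str = "one_se") -> int:
    """Feature count where the CV curve stops improving meaningfully.

    Default ``one_se``: the smallest size whose mean accuracy lies within one
    standard error of the maximum mean over all recorded sizes.
    """
    if rule != "one_se":
        raise ValueError(f"unknown rule {rule!r}")
    means = np.asarray(trace.means)
    best = int(np.argmax(means))
    se = trace.sds[best] / np.sqrt(max(trace.n_trials, 1))
    threshold = means[best] - se
    for size, mean in zip(trace.sizes, means):
        if mean >= threshold - 1e-12:
            return size
    return trace.sizes[-1]


def restrict_candidates(
    feature_names: Sequence[str],
    roi_channels: Sequence[str] = DEFAULT_ROI,
    band: str | None = "gamma",
) -> list[int]:
    """Indices of features with both channels in the ROI (and matching band)."""
    roi = set(roi_channels)
    kept = []
    for index, name in enumerate(feature_names):
        a, b, feature_band = parse_feature_name(name)
        if a in roi and b in roi and (band is None or feature_band == band):
            kept.append(index)
    if not kept:
        raise ValueError("candidate restriction left no features")
    return kept
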