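"""End-to-end orchestration of the biomarker-discovery pipeline.

Glue over the stage modules: cohort -> cleaned sections -> coherence feature
table -> subject-level split -> balanced training sample -> (optional)
floating feature selection -> final classifier -> held-out report with
permutation significance and calibration.  Every stage keeps subject-level
separation; the split objects assert it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import DEFAULT_BANDS, BandTable, feature_columns, feature_table
from .evaluate import (
    EvalReport,
    calibration,
    evaluate,
    fit_final,
    permutation_test,
)
from .preprocess import balanced_sample_indices, clean, segment, subject_split
from .selection import (
    DEFAULT_GAMMA,
    SelectionTrace,
    choose_k,
    restrict_candidates,
    sffs,
    wrapper_cv_score,
)
from .synthetic import CohortSpec, Recording, generate_cohort

POSITIVE = "case"


def cohort_feature_table(
    recordings: Sequence[Recording],
    labels: pd.DataFrame | None = None,
    bands: BandTable = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Clean, segment and featurise a list of recordings."""
    sections = []
    for recording in recordings:
        sections.extend(segment(clean(recording)))
    table = feature_table(sections, recordings[0].montage, bands)
    if labels is not None and "sex" in labels.columns:
        table = table.merge(labels[["subject_id", "sex"]], on="subject_id")
    return table


def synthesize_features(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort and return its section-level feature table."""
    recordings, labels = generate_cohort(spec)
    return cohort_feature_table(recordings, labels)


@dataclass
class ExperimentResult:
    """Everything a run produces: split, selection, model and report."""

    report: EvalReport
    trace: SelectionTrace | None
    selected_features: list[str]
    cv_mean: float
    cv_sd: float
    train_subjects: frozenset[str]
    test_subjects: frozenset[str]
    model: object
    calibrated: object
    train_table: pd.DataFrame
    test_table: pd.DataFrame


def run_experiment(
    table: pd.DataFrame,
    signature: Sequence[str] | None = None,
    select_candidates: Sequence[str] | None = ("roi", "gamma"),
    max_k: int = 20,
    test_fraction: float = 0.10,
    gamma: float = DEFAULT_GAMMA,
    C: float = 1.0,
    selection_repeats: int = 10,
    cv_repeats: int = 10,
    k_folds: int = 10,
    permutation_B: int = 0,
    seed: int = 0,
) -> ExperimentResult:
    """Run the discovery pipeline on a section-level feature table.

    Either a fixed ``signature`` (feature names) is evaluated, or features
    are selected by the floating search over the candidate set (default:
    gamma-band features within the 9-sensor central ROI).  ``permutation_B``
    > 0 adds the label-permutation significance test; the calibrated
    probabilities always yield Brier/ECE.
    """
    names = feature_columns(table)
    groups = (
        table.drop_duplicates("subject_id")
        .set_index("subject_id")["group"]
        .to_dict()
    )
    plan = subject_split(groups, test_fraction=test_fraction, seed=seed)
    train_table = table[table["subject_id"].isin(plan.train_subjects)].reset_index(
        drop=True
    )
    test_table = table[table["subject_id"].isin(plan.test_subjects)].reset_index(
        drop=True
    )

    rows, _ = balanced_sample_indices(
        train_table["subject_id"].to_numpy(), groups, seed=seed + 1
    )
    balanced = train_table.iloc[rows].reset_index(drop=True)
    y_balanced = balanced["group"].to_numpy()
    subjects_balanced = balanced["subject_id"].to_numpy()

    trace = None
    if signature is None:
        if select_candidates == ("roi", "gamma"):
            candidates = restrict_candidates(names)
        elif select_candidates is None:
            candidates = list(range(len(names)))
        else:
            candidates = [names.index(c) for c in select_candidates]
        trace = sffs(
            balanced[names].to_numpy(),
            y_balanced,
            subjects_balanced,
            candidates=candidates,
            max_k=max_k,
            k_folds=k_folds,
            repeats=selection_repeats,
            seed=seed,
            gamma=gamma,
            C=C,
        )
        trace.chosen_k = choose_k(trace)
        subset, _ = trace.best_at(trace.chosen_k)
        signature = [names[i] for i in subset]
    signature = list(signature)

    cv_mean, cv_sd, _ = wrapper_cv_score(
        balanced[signature].to_numpy(),
        y_balanced,
        subjects_balanced,
        k_folds=k_folds,
        repeats=cv_repeats,
        seed=seed + 2,
        gamma=gamma,
        C=C,
    )

    model, calibrated = fit_final(
        balanced[signature].to_numpy(), y_balanced, gamma=gamma, C=C
    )
    report = evaluate(
        model,
        test_table[signature].to_numpy(),
        test_table["group"].to_numpy(),
        test_subjects=test_table["subject_id"].tolist(),
        train_subjects=balanced["subject_id"].tolist(),
        gamma=gamma,
        seed=seed,
    )
    report.extras["cv_mean"] = cv_mean
    report.extras["cv_sd"] = cv_sd
    report.extras["selected_features"] = signature

    probabilities = calibrated.predict_proba(test_table[signature].to_numpy())
    case_col = list(calibrated.classes_).index(POSITIVE)
    outcomes = (test_table["group"].to_numpy() == POSITIVE).astype(float)
    report.brier, report.ece = calibration(probabilities[:, case_col], outcomes)

    if permutation_B > 0:
        p, null_mean, null_sd = permutation_test(
            train_table,
            test_table,
            signature,
            observed_accuracy=report.accuracy,
            gamma=gamma,
            C=C,
            B=permutation_B,
            seed=seed + 3,
        )
        report.permutation_p = p
        report.permutation_null_mean = null_mean
        report.permutation_null_sd = null_sd

    return ExperimentResult(
        report=report,
        trace=trace,
        selected_features=signature,
        cv_mean=cv_mean,
        cv_sd=cv_sd,
        train_subjects=plan.train_subjects,
        test_subjects=plan.test_subjects,
        model=model,
        calibrated=calibrated,
        train_table=train_table,
        test_table=test_table,
    )


def subgroup_rerun(
    table: pd.DataFrame, column: str, value, **experiment_kwargs
) -> ExperimentResult:
    """Re-run the full pipeline on the subjects matching a covariate filter."""
    from .evaluate import subgroup_filter_table

    filtered = subgroup_filter_table(table, column, value)
    result = run_experiment(filtered, **experiment_kwargs)
    result.report.subgroup_filter = f"{column}={value}"
    return result
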