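"""Shared fixtures: a small synthetic cohort and direct feature tables.

The EEG cohort fixtures are deliberately small (few subjects, reduced
sampling rate) so the full generate -> clean -> segment -> featurise chain
stays fast; statistical behaviour of the selection/evaluation stages is
exercised on cheap Gaussian feature tables built by :func:`gaussian_table`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from eegcoh.montage import MontageSpec
from eegcoh.pipeline import cohort_feature_table
from eegcoh.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(n_cases=4, n_controls=4, duration_s=170.0, fs=250.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_table(small_cohort) -> pd.DataFrame:
    recordings, labels = small_cohort
    return cohort_feature_table(recordings, labels)


@pytest.fixture(scope="session")
def montage19() -> MontageSpec:
    return MontageSpec.ten_twenty_19()


def gaussian_table(
    n_cases: int,
    n_controls: int,
    feature_names: list[str],
    informative: dict[str, float] | None = None,
    n_sections: int = 5,
    noise_sd: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Section-level feature table with Gaussian features on the [0, 1] scale.

    ``informative`` maps feature names to the case-vs-control mean shift;
    all features are centred at 0.3 for controls.
    """
    informative = informative or {}
    rng = np.random.default_rng(seed)
    rows = []
    for group, count in (("case", n_cases), ("control", n_controls)):
        for k in range(count):
            subject = f"{group}{k:03d}"
            for section in range(n_sections):
                row = {
                    "subject_id": subject,
                    "group": group,
                    "section_index": section,
                }
                for name in feature_names:
                    shift = informative.get(name, 0.0) if group == "case" else 0.0
                    row[name] = float(
                        np.clip(0.3 + shift + noise_sd * rng.normal(), 0.0, 1.0)
                    )
                rows.append(row)
    return pd.DataFrame(rows)
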