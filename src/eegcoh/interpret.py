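"""Feature-importance ranking and 2-D embedding of the selected features.

Global importance of a feature is the mean absolute Shapley value of the
model's decision value over an explained sample set, with a seeded
background sample drawn from the training data as the masking reference.
Attribution is computed on the margin rather than the calibrated
probability: the sigmoid link is monotone, so the ranking is unchanged.
The t-SNE embedding is reporting-only output; nothing downstream consumes
its coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .shapley import kernel_shap


@dataclass
class ImportanceTable:
    """Per-sample Shapley values and the global mean-absolute ranking."""

    feature_names: tuple[str, ...]
    shapley_values: np.ndarray  # samples x features
    base_values: np.ndarray
    mean_abs: np.ndarray
    order: np.ndarray  # feature indices sorted by descending mean_abs

    @property
    def uninformative(self) -> bool:
        return bool(np.all(self.mean_abs == 0.0))


def shap_importance(
    model,
    background: np.ndarray,
    explain: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
    seed: int = 0,
) -> ImportanceTable:
    """Kernel-Shapley attribution of the decision value for each sample.

    ``background`` and ``explain`` are feature matrices on the model's input
    scale (the model is expected to be a fitted scaler+SVM pipeline; its
    ``decision_function`` is the explained output).
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    explain = np.atleast_2d(np.asarray(explain, dtype=float))
    if background.size == 0:
        raise ValueError("background sample is empty")
    d = explain.shape[1]
    if feature_names is None:
        feature_names = tuple(f"f{j}" for j in range(d))

    def f(X: np.ndarray) -> np.ndarray:
        return np.asarray(model.decision_function(X), dtype=float)

    values = np.empty((explain.shape[0], d))
    bases = np.empty(explain.shape[0])
    for i, x in enumerate(explain):
        values[i], bases[i] = kernel_shap(f, x, background, seed=seed + i)

    mean_abs = np.abs(values).mean(axis=0)
    # stable sort keeps ties in canonical feature order
    order = np.argsort(-mean_abs, kind="stable")
    return ImportanceTable(
        feature_names=tuple(feature_names),
        shapley_values=values,
        base_values=bases,
        mean_abs=mean_abs,
        order=order,
    )


def rank_report(
    table: ImportanceTable, top_n: int = 10
) -> list[tuple[str, float]]:
    """The ``top_n`` features by mean absolute Shapley value."""
    if top_n > len(table.feature_names):
        warnings.warn(
            f"top_n={top_n} exceeds feature count; clamping",
            RuntimeWarning,
            stacklevel=2,
        )
        top_n = len(table.feature_names)
    if table.uninformative:
        warnings.warn(
            "all mean absolute Shapley values are zero; ranking is uninformative",
            RuntimeWarning,
            stacklevel=2,
        )
    return [
        (table.feature_names[j], float(table.mean_abs[j]))
        for j in table.order[:top_n]
    ]


def importance_barplot(table: ImportanceTable, top_n: int = 10, path=None):
    """Horizontal bar plot of the global ranking (optional reporting)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = rank_report(table, top_n)
    names = [n for n, _ in ranked][::-1]
    vals = [v for _, v in ranked][::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(names) + 1))
    ax.barh(names, vals, color="tab:blue")
    ax.set_xlabel("mean |Shapley value| (decision units)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def embed_2d(
    X: np.ndarray,
    perplexity: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """t-SNE embedding of the selected-feature matrix into 2 dimensions."""
    from sklearn.manifold import TSNE

    X = np.asarray(X, dtype=float)
    if perplexity >= X.shape[0]:
        raise ValueError(
            f"perplexity ({perplexity}) must be smaller than the number of "
            f"samples ({X.shape[0]})"
        )
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return tsne.fit_transform(X)


def embedding_scatter(coords: np.ndarray, groups, path=None):
    """Scatter of the 2-D embedding coloured by group (reporting only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(5, 5))
    for group, color in zip(sorted(set(groups)), ("tab:red", "tab:gray", "tab:blue")):
        mask = groups == group
        ax.scatter(coords[mask, 0], coords[mask, 1], s=8, label=str(group), c=color)
    ax.legend(frameon=False)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
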