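"""Shapley-value attribution for black-box models.

The value function is the standard interventional-masking game: a coalition
S fixes the explained sample's values on S and averages the model output
over a background sample for the complement,

    v(S) = mean_b f(x_S, b_{~S}).

Two solvers are provided.  ``exact_shapley`` enumerates all 2^d coalitions
and applies the classic weighted marginal-contribution formula — exact but
exponential, intended for d <= ~15.  ``kernel_shap`` solves the weighted
least-squares formulation of the same game (Shapley kernel weights, with the
empty and full coalitions imposed as equality constraints); with full
coalition enumeration its solution coincides with the exact values, and for
larger d it subsamples coalitions by the kernel weights.  Both are
deterministic given a seed, and both satisfy local accuracy
(sum_j phi_j + base = f(x)) by construction.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Callable

import numpy as np

ModelFn = Callable[[np.ndarray], np.ndarray]


def _coalition_value(
    model: ModelFn, x: np.ndarray, background: np.ndarray, mask: np.ndarray
) -> float:
    synthetic = background.copy()
    synthetic[:, mask] = x[mask]
    return float(np.mean(model(synthetic)))


def _all_masks(d: int) -> np.ndarray:
    masks = np.zeros((2**d, d), dtype=bool)
    for s in range(2**d):
        for j in range(d):
            masks[s, j] = (s >> j) & 1
    return masks


def exact_shapley(
    model: ModelFn, x: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact Shapley values by coalition enumeration.

    Returns (phi, base) with base = v(empty set).
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = x.size
    if d > 20:
        raise ValueError("exact enumeration is limited to d <= 20 features")

    values: dict[frozenset[int], float] = {}
    features = range(d)
    for size in range(d + 1):
        for subset in combinations(features, size):
            mask = np.zeros(d, dtype=bool)
            mask[list(subset)] = True
            values[frozenset(subset)] = _coalition_value(model, x, background, mask)

    phi = np.zeros(d)
    for j in features:
        others = [f for f in features if f != j]
        for size in range(d):
            weight = 1.0 / (d * comb(d - 1, size))
            for subset in combinations(others, size):
                s = frozenset(subset)
                phi[j] += weight * (values[s | {j}] - values[s])
    return phi, values[frozenset()]


def kernel_shap(
    model: ModelFn,
    x: np.ndarray,
    background: np.ndarray,
    n_coalitions: int | None = None,
    max_exhaustive: int = 15,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Kernel-weighted least-squares Shapley approximation.

    For d <= ``max_exhaustive`` every proper coalition is used, which makes
    the solution exact; otherwise ``n_coalitions`` coalitions are sampled
    with probability proportional to the Shapley kernel weight of their
    size.  Returns (phi, base).
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background sample is empty")
    d = x.size
    base = _coalition_value(model, x, background, np.zeros(d, dtype=bool))
    full = _coalition_value(model, x, background, np.ones(d, dtype=bool))
    if d == 1:
        return np.array([full - base]), base

    if d <= max_exhaustive:
        masks = _all_masks(d)
        sizes = masks.sum(axis=1)
        proper = (sizes > 0) & (sizes < d)
        masks = masks[proper]
        sizes = sizes[proper]
        weights = np.array(
            [(d - 1) / (comb(d, s) * s * (d - s)) for s in sizes]
        )
    else:
        if n_coalitions is None:
            n_coalitions = 200 * d
        rng = np.random.default_rng(seed)
        size_weights = np.array(
            [(d - 1) / (s * (d - s)) for s in range(1, d)]
        )
        size_probs = size_weights / size_weights.sum()
        drawn_sizes = rng.choice(np.arange(1, d), size=n_coalitions, p=size_probs)
        masks = np.zeros((n_coalitions, d), dtype=bool)
        for row, s in enumerate(drawn_sizes):
            masks[row, rng.choice(d, size=s, replace=False)] = True
        weights = np.ones(n_coalitions)

    values = np.array(
        [_coalition_value(model, x, background, mask) for mask in masks]
    )

    # solve weighted least squares subject to sum(phi) = full - base by
    # eliminating the last coefficient
    Z = masks.astype(float)
    target = values - base - Z[:, -1] * (full - base)
    A = Z[:, :-1] - Z[:, [-1]]
    W = np.sqrt(weights)
    coef, *_ = np.linalg.lstsq(A * W[:, None], target * W, rcond=None)
    phi = np.empty(d)
    phi[:-1] = coef
    phi[-1] = (full - base) - coef.sum()
    return phi, base
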