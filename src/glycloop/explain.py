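"""Model-agnostic attribution for the dual-prediction system.

Shapley values are computed by exact enumeration of all feature subsets,
with the value of a coalition realized as the marginal (interventional)
expectation over a background sample: features outside the coalition are
replaced by background rows and the model's mean output is taken. With 13
features this costs 2^13 coalition evaluations, batched into a single
model call, and the exact values double as the oracle for the seeded
permutation-sampling estimator provided for larger feature spaces.

Pairwise Shapley interaction values quantify the joint contribution of two
features beyond their individual effects; the headline use is the
carbohydrate x bolus interaction. The interaction matrix stores the
pairwise terms off-diagonal and the main effects (per-feature value minus
its interactions) on the diagonal, so each row sums to the feature's
Shapley value and the whole matrix sums to f(x) - E[f].

Local surrogates follow the LIME recipe: Gaussian perturbations around the
instance, exponential-kernel proximity weights, and a weighted ridge
regression whose penalty realizes the complexity term; all features are
retained so that full importance rankings can be aggregated per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .errors import FeatureError

logger = logging.getLogger(__name__)

EXACT_LIMIT = 16   # max features for exact subset enumeration

PredictFn = Callable[[np.ndarray], np.ndarray]


@dataclass
class Attribution:
    """Per-feature Shapley values with their additive decomposition."""

    values: np.ndarray       # phi_i
    base_value: float        # E[f] over the background
    fx: float                # f(x)

    @property
    def efficiency_gap(self) -> float:
        return float(self.fx - self.base_value - self.values.sum())


@dataclass
class InteractionMatrix:
    """Symmetric pairwise Shapley interactions; diagonal = main effects."""

    matrix: np.ndarray
    attribution: Attribution

    def pair(self, i: int, j: int) -> float:
        return float(self.matrix[i, j])


@dataclass
class LocalSurrogate:
    """Weighted-ridge local explanation around one instance."""

    intercept: float
    weights: np.ndarray
    kernel_width: float
    n_samples: int
    seed: int
    r2: float                 # weighted goodness of the local fit

    def ranking(self) -> np.ndarray:
        """Feature ranks, 1 = largest absolute weight."""
        order = np.argsort(-np.abs(self.weights), kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        return ranks


# ---------------------------------------------------------------------------
# exact Shapley machinery
# ---------------------------------------------------------------------------

def _coalition_values(
    predict: PredictFn, x: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """v(S) for every subset bitmask S: mean prediction with off-coalition
    features drawn from the background sample."""
    x = np.asarray(x, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    d = x.size
    if bg.shape[1] != d:
        raise FeatureError("background dimension does not match the instance")
    if bg.shape[0] == 0:
        raise FeatureError("background sample must be non-empty")
    n_subsets = 1 << d
    n_bg = bg.shape[0]
    # one big batch: subset-major blocks of background rows
    tiled = np.tile(bg, (n_subsets, 1))
    for i in range(d):
        # rows of subsets containing feature i get x[i]
        masks = (np.arange(n_subsets) >> i) & 1
        rows = np.repeat(masks.astype(bool), n_bg)
        tiled[rows, i] = x[i]
    preds = np.asarray(predict(tiled), dtype=float).ravel()
    return preds.reshape(n_subsets, n_bg).mean(axis=1)


def shapley_values(
    predict: PredictFn,
    x: np.ndarray,
    background: np.ndarray,
    _values: np.ndarray | None = None,
) -> Attribution:
    """Exact Shapley attribution of ``predict`` at ``x``.

    Enumerates all feature subsets (feasible up to 16 features); beyond
    that use :func:`shapley_values_sampled`.
    """
    x = np.asarray(x, dtype=float).ravel()
    d = x.size
    if d > EXACT_LIMIT:
        raise FeatureError(
            f"{d} features exceeds the exact enumeration limit "
            f"({EXACT_LIMIT}); use shapley_values_sampled")
    v = _coalition_values(predict, x, background) if _values is None else _values
    sizes = np.array([bin(m).count("1") for m in range(1 << d)])
    w = np.array([factorial(s) * factorial(d - s - 1) / factorial(d)
                  for s in range(d)])
    phi = np.zeros(d)
    for m in range(1 << d):
        s = sizes[m]
        for i in range(d):
            if not (m >> i) & 1:
                phi[i] += w[s] * (v[m | (1 << i)] - v[m])
    return Attribution(values=phi, base_value=float(v[0]),
                       fx=float(v[(1 << d) - 1]))


def shapley_interactions(
    predict: PredictFn, x: np.ndarray, background: np.ndarray
) -> InteractionMatrix:
    """Exact pairwise Shapley interaction matrix at ``x``."""
    x = np.asarray(x, dtype=float).ravel()
    d = x.size
    if d > EXACT_LIMIT:
        raise FeatureError(
            f"{d} features exceeds the exact enumeration limit ({EXACT_LIMIT})")
    v = _coalition_values(predict, x, background)
    attribution = shapley_values(predict, x, background, _values=v)
    sizes = np.array([bin(m).count("1") for m in range(1 << d)])
    w2 = np.array([factorial(s) * factorial(max(d - s - 2, 0)) / factorial(d)
                   for s in range(max(d - 1, 1))])
    mat = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            bij = (1 << i) | (1 << j)
            total = 0.0
            for m in range(1 << d):
                if m & bij:
                    continue
                total += w2[sizes[m]] * (
                    v[m | bij] - v[m | (1 << i)] - v[m | (1 << j)] + v[m]
                )
            mat[i, j] = mat[j, i] = total
    off_sums = mat.sum(axis=1)
    np.fill_diagonal(mat, attribution.values - off_sums)
    return InteractionMatrix(matrix=mat, attribution=attribution)


def shapley_values_sampled(
    predict: PredictFn,
    x: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
) -> Attribution:
    """Seeded Monte-Carlo permutation estimator of the Shapley values."""
    x = np.asarray(x, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    d = x.size
    rng = np.random.default_rng(seed)
    phi = np.zeros(d)
    base = float(np.mean(predict(bg)))
    fx = float(np.asarray(predict(x[None, :])).ravel()[0])
    for _ in range(n_permutations):
        perm = rng.permutation(d)
        current = bg.copy()
        prev = float(np.mean(predict(current)))
        for i in perm:
            current[:, i] = x[i]
            cur = float(np.mean(predict(current)))
            phi[i] += cur - prev
            prev = cur
    phi /= n_permutations
    return Attribution(values=phi, base_value=base, fx=fx)


# ---------------------------------------------------------------------------
# LIME-style local surrogate
# ---------------------------------------------------------------------------

def lime_explain(
    predict: PredictFn,
    x: np.ndarray,
    training_sd: np.ndarray,
    n_samples: int = 5000,
    kernel_width: float | None = None,
    seed: int = 0,
    ridge_alpha: float = 1.0,
) -> LocalSurrogate:
    """Fit a weighted ridge surrogate to ``predict`` around ``x``.

    Perturbations are Gaussian with the per-feature training standard
    deviations; proximity pi(x, z) = exp(-dist^2 / kernel_width^2) with the
    distance taken in sd-standardized units. The ridge penalty plays the
    complexity role; all features are retained.
    """
    x = np.asarray(x, dtype=float).ravel()
    sd = np.asarray(training_sd, dtype=float).ravel()
    if n_samples < 50:
        raise ValueError("n_samples must be at least 50")
    if np.any(sd <= 0):
        raise FeatureError("degenerate perturbation variance (sd <= 0)")
    d = x.size
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)
    rng = np.random.default_rng(seed)
    Z = x + rng.normal(0.0, sd, size=(n_samples, d))
    dist = np.linalg.norm((Z - x) / sd, axis=1)
    pi = np.exp(-(dist**2) / kernel_width**2)
    fz = np.asarray(predict(Z), dtype=float).ravel()
    model = Ridge(alpha=ridge_alpha)
    model.fit(Z, fz, sample_weight=pi)
    pred = model.predict(Z)
    resid = np.average((fz - pred) ** 2, weights=pi)
    var = np.average((fz - np.average(fz, weights=pi)) ** 2, weights=pi)
    r2 = 1.0 - resid / var if var > 0 else 1.0
    return LocalSurrogate(
        intercept=float(model.intercept_), weights=model.coef_.copy(),
        kernel_width=float(kernel_width), n_samples=n_samples, seed=seed,
        r2=float(r2),
    )


# ---------------------------------------------------------------------------
# aggregation views
# ---------------------------------------------------------------------------

def aggregate_shap(
    records: Sequence[dict], feature_names: Sequence[str]
) -> pd.DataFrame:
    """Mean Shapley value per feature per (model, iteration).

    Each record: {"model": str, "iteration": int, "phi": array-like of one
    or more attribution vectors}.
    """
    if not records:
        raise ValueError("need at least one attribution record")
    rows = []
    for rec in records:
        phi = np.atleast_2d(np.asarray(rec["phi"], dtype=float))
        mean_phi = phi.mean(axis=0)
        for name, val in zip(feature_names, mean_phi):
            rows.append(dict(model=rec["model"], iteration=rec["iteration"],
                             feature=name, mean_shap=float(val)))
    return pd.DataFrame(rows)


def aggregate_lime_ranks(
    records: Sequence[dict], feature_names: Sequence[str]
) -> pd.DataFrame:
    """Mean LIME importance rank per feature per cluster.

    Each record: {"cluster": key, "surrogate": LocalSurrogate}.
    """
    if not records:
        raise ValueError("need at least one surrogate record")
    rows = []
    for rec in records:
        ranks = rec["surrogate"].ranking()
        for name, r in zip(feature_names, ranks):
            rows.append(dict(cluster=str(rec["cluster"]), feature=name, rank=int(r)))
    df = pd.DataFrame(rows)
    return (df.groupby(["cluster", "feature"])["rank"].mean()
            .rename("mean_rank").reset_index())


__all__ = [
    "Attribution", "InteractionMatrix", "LocalSurrogate",
    "shapley_values", "shapley_interactions", "shapley_values_sampled",
    "lime_explain", "aggregate_shap", "aggregate_lime_ranks", "EXACT_LIMIT",
]
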