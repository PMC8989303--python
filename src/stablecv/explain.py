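"""Permutation feature importance and partial dependence.

Both are computed per project on fitted blueprints and aggregated across
projects with Student-t 95% confidence intervals, which is what makes the
resulting importances and dependence curves stable enough to drive feature
reduction and interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import CATEGORICAL, NUMERIC, FeatureTable
from .metrics_stability import (PFIList, _t_ci, logloss, normalize_importances,
                                rank_importances)

#: Above this many distinct values a numeric PDP grid switches to quantiles.
MAX_GRID = 25


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------

def raw_permutation_importance(model, frame: pd.DataFrame, y: np.ndarray,
                               n_permutations: int = 10,
                               rng: np.random.Generator | None = None) -> np.ndarray:
    """Mean LogLoss increase per feature over independent column shuffles.

    Shuffling a raw feature column and re-encoding is equivalent to applying
    the same row permutation to that feature's already-encoded column block
    (all encoders here are row-wise per column), so the design is transformed
    once and blocks are permuted in place — exact and much faster.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    X = model.preprocessor.transform(frame)
    base = logloss(y, model.predict_proba_matrix(X))
    out = np.empty(len(model.features))
    n = X.shape[0]
    for fi, feature in enumerate(model.features):
        block = model.blocks[feature]
        original = X[:, block].copy()
        total = 0.0
        for _ in range(n_permutations):
            sigma = rng.permutation(n)
            X[:, block] = original[sigma]
            total += logloss(y, model.predict_proba_matrix(X))
        X[:, block] = original
        out[fi] = total / n_permutations - base
    return out


def permutation_importance(model, table: FeatureTable, n_permutations: int = 10,
                           seed: int = 0) -> PFIList:
    """Normalized permutation importance of every model feature on a table.

    Raw importances (mean LogLoss increase) are floored at zero and scaled to
    a maximum of one.
    """
    unknown = [f for f in model.features if f not in table.features]
    if unknown:
        raise ValueError(f"model features absent from table: {unknown}")
    raw = raw_permutation_importance(
        model, table.frame[model.features], table.y,
        n_permutations=n_permutations, rng=np.random.default_rng(seed))
    return normalize_importances(model.features, raw)


def aggregate_pfi(lists: Sequence[PFIList]) -> PFIList:
    """Per-feature mean normalized importance with t-CIs across projects."""
    if len(lists) < 2:
        raise ValueError("need at least 2 pFI lists to aggregate")
    feats = list(lists[0].features)
    fset = set(feats)
    for pl in lists[1:]:
        if set(pl.features) != fset:
            raise ValueError("pFI lists must share a common feature set")
    mat = np.asarray([[pl.importance_of(f) for f in feats] for pl in lists])
    means, lows, highs = [], [], []
    for j in range(mat.shape[1]):
        mu, lo, hi = _t_ci(mat[:, j])
        means.append(mu); lows.append(lo); highs.append(hi)
    return PFIList(features=tuple(feats), importances=tuple(means),
                   ci_low=tuple(lows), ci_high=tuple(highs))


# ---------------------------------------------------------------------------
# Partial dependence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PDPGrid:
    """Average prediction over the training table at forced feature values."""

    feature: str
    grid: tuple
    values: tuple[float, ...]
    ci_low: tuple[float, ...] | None = None
    ci_high: tuple[float, ...] | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"feature": self.feature, "grid_value": self.grid,
                            "mean": self.values})
        if self.ci_low is not None:
            out["ci_low"] = self.ci_low
            out["ci_high"] = self.ci_high
        return out


def pdp_grid_values(table: FeatureTable, feature: str):
    """Default grid: all categorical levels, or numeric unique values when
    there are at most 25, else 25 equally spaced quantiles of the full table."""
    col = table.frame[feature].dropna()
    if table.kinds[feature] == CATEGORICAL:
        return tuple(sorted({str(v) for v in col}))
    uniq = np.unique(col.to_numpy(dtype=float))
    if uniq.size <= MAX_GRID:
        return tuple(float(v) for v in uniq)
    qs = np.linspace(0, 100, MAX_GRID)
    return tuple(float(v) for v in np.unique(np.percentile(uniq, qs)))


def partial_dependence(model, table: FeatureTable, feature: str,
                       grid: Sequence | None = None) -> PDPGrid:
    """PDP of one feature: force every training record to each grid value,
    predict, and average the probabilities."""
    if feature not in table.features:
        raise ValueError(f"feature {feature!r} not in table")
    grid = pdp_grid_values(table, feature) if grid is None else tuple(grid)
    if len(grid) == 0:
        raise ValueError("empty PDP grid")
    frame = table.frame[model.features].copy()
    values = []
    for v in grid:
        frame[feature] = v
        values.append(float(np.mean(model.predict_proba(frame))))
    return PDPGrid(feature=feature, grid=grid, values=tuple(values))


def project_partial_dependence(result, table: FeatureTable, feature: str,
                               grid: Sequence | None = None) -> PDPGrid:
    """One project's PDP: mean of the k fold models' PDPs.

    Fold models (each fitted on k-1 folds) carry the project's partitioning
    arrangement into the curve, so per-project PDPs genuinely vary and the
    cross-project aggregate has a meaningful CI. Requires
    ``fit_blueprint(..., keep_fold_models=True)``.
    """
    if result.fold_models is None:
        raise ValueError("project was fitted without keep_fold_models=True")
    grid = pdp_grid_values(table, feature) if grid is None else tuple(grid)
    per_fold = [partial_dependence(m, table, feature, grid)
                for m in result.fold_models]
    values = np.mean([g.values for g in per_fold], axis=0)
    return PDPGrid(feature=feature, grid=grid,
                   values=tuple(float(v) for v in values))


def aggregate_pdp(grids: Sequence[PDPGrid]) -> PDPGrid:
    """Pointwise mean + t-CI of per-project PDPs sharing one grid."""
    if len(grids) < 2:
        raise ValueError("need at least 2 PDP grids to aggregate")
    first = grids[0]
    for g in grids[1:]:
        if g.feature != first.feature or g.grid != first.grid:
            raise ValueError("PDP grids must be identical across projects")
    mat = np.asarray([g.values for g in grids])
    means, lows, highs = [], [], []
    for j in range(mat.shape[1]):
        mu, lo, hi = _t_ci(mat[:, j])
        means.append(mu); lows.append(lo); highs.append(hi)
    return PDPGrid(feature=first.feature, grid=first.grid,
                   values=tuple(means), ci_low=tuple(lows), ci_high=tuple(highs))
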