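"""Performance metrics, cross-project aggregation, and stability analyses.

Implements the two stability metrics — the standardized performance CI width
(95% CI width over mean, as a percent) and the feature rank instability (FRI,
an L1 distance on importance-rank vectors) — plus the two sampling analyses
that characterize how both behave as more cross-validation projects are
aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CLIP = 1e-15


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------

def logloss(targets: Sequence[float], probabilities: Sequence[float]) -> float:
    """Mean negative log-likelihood of binary targets under probabilities.

    Probabilities are clipped to ``(1e-15, 1 - 1e-15)`` so the loss is finite.
    """
    y = np.asarray(targets, dtype=float)
    p = np.clip(np.asarray(probabilities, dtype=float), CLIP, 1.0 - CLIP)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError("targets and probabilities must have equal length")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def auc(targets: Sequence[float], scores: Sequence[float]) -> float:
    """Area under the ROC curve, Mann-Whitney form: P(s+ > s-) + P(tie)/2."""
    y = np.asarray(targets, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc requires both classes present")
    ranks = stats.rankdata(s)  # midranks handle ties
    r_pos = float(np.sum(ranks[y == 1]))
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggregateResult:
    """Mean and two-sided 95% CI of one scalar quantity across projects."""

    name: str
    n_projects: int
    mean: float
    ci_low: float
    ci_high: float
    values: tuple[float, ...]

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


def _t_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    n = values.size
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    half = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / np.sqrt(n))
    return mean, mean - half, mean + half


def aggregate(values: Sequence[float], name: str = "quantity") -> AggregateResult:
    """Student-t mean and 95% CI over per-project scalar values (n >= 2)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("aggregation requires at least 2 values")
    mean, lo, hi = _t_ci(arr)
    return AggregateResult(name=name, n_projects=int(arr.size), mean=mean,
                           ci_low=lo, ci_high=hi, values=tuple(arr.tolist()))


def standardized_ci_width(agg: AggregateResult) -> float:
    """95% CI width divided by the mean, as a percent."""
    if agg.mean == 0:
        raise ValueError("standardized CI width undefined for zero mean")
    return float(agg.ci_width / agg.mean * 100.0)


# ---------------------------------------------------------------------------
# pFI lists and FRI
# ---------------------------------------------------------------------------

def rank_importances(features: Sequence[str], importances: Sequence[float]) -> np.ndarray:
    """Ranks with 1 = most important; ties broken by ascending feature name."""
    imp = np.asarray(importances, dtype=float)
    name_order = np.argsort(np.argsort(np.asarray(features, dtype=object)))
    order = np.lexsort((name_order, -imp))  # primary: descending importance
    ranks = np.empty(imp.size, dtype=int)
    ranks[order] = np.arange(1, imp.size + 1)
    return ranks


@dataclass(frozen=True)
class PFIList:
    """Normalized permutation feature importances with derived ranks.

    Importances are non-negative and scaled so the maximum equals 1 whenever
    any importance is positive.
    """

    features: tuple[str, ...]
    importances: tuple[float, ...]
    ci_low: tuple[float, ...] | None = None
    ci_high: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.features) != len(self.importances):
            raise ValueError("features and importances must align")
        imp = np.asarray(self.importances)
        if imp.size and imp.min() < -1e-12:
            raise ValueError("importances must be non-negative (floor first)")

    @property
    def ranks(self) -> dict[str, int]:
        r = rank_importances(self.features, self.importances)
        return dict(zip(self.features, (int(x) for x in r)))

    def importance_of(self, feature: str) -> float:
        return dict(zip(self.features, self.importances))[feature]

    def restricted(self, features: Sequence[str]) -> "PFIList":
        """Restrict to a feature subset (importances kept, not renormalized)."""
        imp = dict(zip(self.features, self.importances))
        return PFIList(features=tuple(features),
                       importances=tuple(imp[f] for f in features))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"feature": self.features,
                            "importance": self.importances})
        out["rank"] = rank_importances(self.features, self.importances)
        if self.ci_low is not None:
            out["ci_low"] = self.ci_low
            out["ci_high"] = self.ci_high
        return out.sort_values("rank").reset_index(drop=True)


def normalize_importances(features: Sequence[str], raw: Sequence[float]) -> PFIList:
    """Floor raw importances at 0, then scale to a maximum of 1."""
    imp = np.maximum(np.asarray(raw, dtype=float), 0.0)
    if imp.size and imp.max() > 0:
        imp = imp / imp.max()
    return PFIList(features=tuple(features), importances=tuple(imp.tolist()))


def fri(p: PFIList, q: PFIList) -> float:
    """Feature rank instability: sum of absolute rank differences.

    Ranks are recomputed within the shared feature set, so partially
    overlapping lists are compared on equal footing.
    """
    shared = [f for f in p.features if f in set(q.features)]
    if not shared:
        raise ValueError("no shared features")
    rp = rank_importances(shared, [p.importance_of(f) for f in shared])
    rq = rank_importances(shared, [q.importance_of(f) for f in shared])
    return float(np.sum(np.abs(rp - rq)))


def fri_bottom_k(p_reference: PFIList, q: PFIList, k: int) -> float:
    """FRI restricted to the ``k`` least-important features of the reference
    list, using ranks computed over the full shared set."""
    if k <= 0:
        raise ValueError("k must be positive")
    shared = [f for f in p_reference.features if f in set(q.features)]
    if k > len(shared):
        raise ValueError("k exceeds shared feature count")
    rp = rank_importances(shared, [p_reference.importance_of(f) for f in shared])
    rq = rank_importances(shared, [q.importance_of(f) for f in shared])
    bottom = np.argsort(-rp)[:k]  # largest rank numbers = least important
    return float(np.sum(np.abs(rp[bottom] - rq[bottom])))


# ---------------------------------------------------------------------------
# Sampling analyses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityCurve:
    """Expected metric value (with 95% CI) per number of projects aggregated."""

    metric: str
    sizes: tuple[int, ...]
    means: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "mean": self.means,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})

    def value_at(self, size: int) -> float:
        return self.means[self.sizes.index(size)]


def _metric_values(results, metric: str) -> np.ndarray:
    vals = []
    for r in results:
        if hasattr(r, metric):
            vals.append(getattr(r, metric))
        else:
            vals.append(float(r))
    return np.asarray(vals, dtype=float)


def precision_sampling_analysis(results, n_draws: int = 1000, seed: int = 0,
                                metric: str = "cv_logloss",
                                m_max: int | None = None) -> StabilityCurve:
    """Expected standardized performance CI width by aggregate size.

    Each replicate samples projects one at a time without replacement and
    recomputes the standardized CI width of the growing aggregate at every
    size from 2 up to ``m_max``; means and 95% CIs are taken over replicates.
    ``results`` may be ProjectResults (read via ``metric``) or raw scalars.
    """
    values = np.sort(_metric_values(results, metric))  # input-order invariance
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 project results")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    m_max = n if m_max is None else min(m_max, n)

    rng = np.random.default_rng(seed)
    # draws x projects matrix of sampled orderings (without replacement)
    perms = np.argsort(rng.random((n_draws, n)), axis=1)
    sampled = values[perms][:, :m_max]  # (n_draws, m_max)

    m = np.arange(1, m_max + 1, dtype=float)
    csum = np.cumsum(sampled, axis=1)
    csum2 = np.cumsum(sampled ** 2, axis=1)
    means = csum / m
    # unbiased variance of the first m samples; guard m=1 (unused below)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.maximum(csum2 - m * means ** 2, 0.0) / np.maximum(m - 1.0, 1.0)
        tcrit = stats.t.ppf(0.975, np.maximum(m - 1.0, 1.0))
        width = 2.0 * tcrit * np.sqrt(var / m)
        std_width = width / means * 100.0

    sizes = np.arange(2, m_max + 1)
    per_size = std_width[:, 1:]  # drop m=1
    out_mean, out_lo, out_hi = [], [], []
    for j in range(per_size.shape[1]):
        col = per_size[:, j]
        if n_draws >= 2:
            mu, lo, hi = _t_ci(col)
        else:
            mu = float(col[0]); lo = hi = mu
        out_mean.append(mu); out_lo.append(lo); out_hi.append(hi)
    return StabilityCurve(metric=f"standardized_ci_width({metric})",
                          sizes=tuple(int(s) for s in sizes),
                          means=tuple(out_mean), ci_low=tuple(out_lo),
                          ci_high=tuple(out_hi))


def _pfi_matrix(results) -> tuple[list[str], np.ndarray]:
    lists = [r.pfi if hasattr(r, "pfi") else r for r in results]
    feats = list(lists[0].features)
    fset = set(feats)
    for pl in lists[1:]:
        if set(pl.features) != fset:
            raise ValueError("all pFI lists must share one feature set")
    mat = np.asarray([[pl.importance_of(f) for f in feats] for pl in lists])
    return feats, mat


def fri_sampling_analysis(results, n_draws: int = 1000, seed: int = 0,
                          bottom_k: int | None = None,
                          m_max: int | None = None) -> StabilityCurve:
    """Expected FRI between consecutive project aggregates, by aggregate size.

    Per replicate: sample projects without replacement; at each size ``m >= 2``
    rank features by their mean importance over the aggregate and compute FRI
    against the previous aggregate's ranking (for ``m = 2`` the previous
    aggregate is the first sampled project alone). With ``bottom_k`` the sum
    runs only over the ``k`` least-important features of the smaller
    aggregate, using full-list ranks.
    """
    feats, mat = _pfi_matrix(results)
    mat = mat[np.lexsort(mat.T[::-1])]  # input-order invariance
    n, f = mat.shape
    if n < 2:
        raise ValueError("need at least 2 project results")
    m_max = n if m_max is None else min(m_max, n)

    name_order = np.argsort(np.argsort(np.asarray(feats, dtype=object)))
    rng = np.random.default_rng(seed)
    sizes = np.arange(2, m_max + 1)
    curves = np.empty((n_draws, sizes.size))

    for d in range(n_draws):
        perm = rng.permutation(n)
        cum = np.cumsum(mat[perm[:m_max]], axis=0)
        means = cum / np.arange(1, m_max + 1)[:, None]
        ranks = np.empty_like(means, dtype=int)
        for i in range(m_max):
            order = np.lexsort((name_order, -means[i]))
            ranks[i, order] = np.arange(1, f + 1)
        diff = np.abs(ranks[1:] - ranks[:-1])  # row i: size i+2 vs previous
        if bottom_k is None:
            curves[d] = diff.sum(axis=1)
        else:
            for i in range(sizes.size):
                bottom = np.argsort(-ranks[i])[:bottom_k]  # reference: smaller aggregate
                curves[d, i] = diff[i, bottom].sum()

    out_mean, out_lo, out_hi = [], [], []
    for j in range(sizes.size):
        col = curves[:, j]
        if n_draws >= 2:
            mu, lo, hi = _t_ci(col)
        else:
            mu = float(col[0]); lo = hi = mu
        out_mean.append(mu); out_lo.append(lo); out_hi.append(hi)
    label = "fri" if bottom_k is None else f"fri_bottom_{bottom_k}"
    return StabilityCurve(metric=label, sizes=tuple(int(s) for s in sizes),
                          means=tuple(out_mean), ci_low=tuple(out_lo),
                          ci_high=tuple(out_hi))
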