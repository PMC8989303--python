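"""External-validation scoring and train-vs-validation drift auditing.

Scoring aggregates per-patient predictions and best-F1 thresholds across the
fitted projects and classifies by mean probability vs mean threshold. The
drift audit computes a per-feature population stability index (PSI) with
drift classes, and clusters the pooled cohorts (2-D nonlinear embedding +
density-based hierarchical clustering) to surface subpopulations that shrank
or grew between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import CATEGORICAL, NUMERIC, FeatureTable
from .metrics_stability import AggregateResult, _t_ci, aggregate

PSI_FLOOR = 1e-4
PSI_MODERATE = 0.1
PSI_SIGNIFICANT = 0.25

DRIFT_NONE = "none"
DRIFT_MODERATE = "moderate"
DRIFT_SIGNIFICANT = "significant"


# ---------------------------------------------------------------------------
# Validation scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationScore:
    """Aggregated validation predictions and the derived confusion matrix."""

    mean_probabilities: pd.Series
    prob_ci_low: pd.Series
    prob_ci_high: pd.Series
    threshold: AggregateResult
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def confusion_matrix(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}

    def to_dict(self) -> dict:
        return {
            "mean_best_f1_threshold": self.threshold.mean,
            "threshold_ci": [self.threshold.ci_low, self.threshold.ci_high],
            "confusion_matrix": self.confusion_matrix,
            "mean_probabilities": {str(k): float(v) for k, v
                                   in self.mean_probabilities.items()},
        }


def score_validation(results: Sequence, validation_table: FeatureTable) -> ValidationScore:
    """Score a validation cohort with per-project models and thresholds.

    Each project's full-data model (with its training-fitted preprocessing)
    predicts every validation patient; a patient is classified positive iff
    the mean probability strictly exceeds the mean best-F1 threshold.
    """
    models = [r.model for r in results]
    if any(m is None for m in models):
        raise ValueError("results must carry fitted models (refit_full=True)")
    needed = models[0].features
    missing = [f for f in needed if f not in validation_table.features]
    if missing:
        raise ValueError(f"validation table missing parsimonious features: {missing}")

    frame = validation_table.frame[needed]
    probs = np.vstack([m.predict_proba(frame) for m in models])  # (projects, patients)
    mean_p = probs.mean(axis=0)
    if len(models) >= 2:
        ci = np.array([_t_ci(probs[:, j]) for j in range(probs.shape[1])])
        lo, hi = ci[:, 1], ci[:, 2]
        thr = aggregate([r.best_f1_threshold for r in results], "best_f1_threshold")
    else:
        lo = hi = mean_p
        t = float(results[0].best_f1_threshold)
        thr = AggregateResult("best_f1_threshold", 1, t, t, t, (t,))

    y = validation_table.y
    pred = mean_p > thr.mean
    idx = validation_table.patients
    return ValidationScore(
        mean_probabilities=pd.Series(mean_p, index=idx, name="mean_probability"),
        prob_ci_low=pd.Series(lo, index=idx),
        prob_ci_high=pd.Series(hi, index=idx),
        threshold=thr,
        tp=int(np.sum(pred & (y == 1))), fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))), fn=int(np.sum(~pred & (y == 1))))


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def psi(train_values: Sequence, valid_values: Sequence, n_bins: int = 10,
        kind: str = NUMERIC) -> float:
    """Population stability index between two samples of one feature.

    Numeric: bins at training quantiles; categorical: one bin per level over
    the union of levels. Empty-bin proportions are floored at 1e-4.
    """
    train = pd.Series(list(train_values)).dropna()
    valid = pd.Series(list(valid_values)).dropna()
    if train.empty or valid.empty:
        raise ValueError("both samples must be non-empty")

    if kind == NUMERIC:
        t = train.to_numpy(dtype=float)
        v = valid.to_numpy(dtype=float)
        edges = np.unique(np.quantile(t, np.linspace(0, 1, n_bins + 1)[1:-1]))
        t_counts = np.bincount(np.searchsorted(edges, t, side="right"),
                               minlength=edges.size + 1)
        v_counts = np.bincount(np.searchsorted(edges, v, side="right"),
                               minlength=edges.size + 1)
    else:
        levels = sorted({str(x) for x in train} | {str(x) for x in valid})
        t_counts = np.asarray([(train.astype(str) == l).sum() for l in levels])
        v_counts = np.asarray([(valid.astype(str) == l).sum() for l in levels])

    t_prop = np.maximum(t_counts / t_counts.sum(), PSI_FLOOR)
    v_prop = np.maximum(v_counts / v_counts.sum(), PSI_FLOOR)
    return float(np.sum((v_prop - t_prop) * np.log(v_prop / t_prop)))


def classify_drift(psi_value: float) -> str:
    """<0.1 none; [0.1, 0.25] moderate; >0.25 significant."""
    if psi_value < 0:
        raise ValueError("PSI cannot be negative")
    if psi_value < PSI_MODERATE:
        return DRIFT_NONE
    if psi_value <= PSI_SIGNIFICANT:
        return DRIFT_MODERATE
    return DRIFT_SIGNIFICANT


def feature_psi(train_table: FeatureTable, valid_table: FeatureTable,
                features: Sequence[str], n_bins: int = 10) -> pd.DataFrame:
    """Per-feature PSI and drift class between two cohorts."""
    rows = []
    for f in features:
        value = psi(train_table.frame[f], valid_table.frame[f],
                    n_bins=n_bins, kind=train_table.kinds[f])
        rows.append({"feature": f, "psi": value, "drift_class": classify_drift(value)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class DriftReport:
    """Cluster labels over the pooled cohorts plus per-feature PSI."""

    psi_table: pd.DataFrame | None
    labels: pd.Series            # cluster label per retained patient (-1 = noise)
    cohort: pd.Series            # "train" | "valid" per retained patient
    data: pd.DataFrame           # retained raw feature rows
    embedding: np.ndarray        # (retained, 2)
    n_removed: int               # records dropped by listwise deletion
    features: tuple[str, ...]

    def cluster_cohort_counts(self) -> pd.DataFrame:
        return (pd.crosstab(self.labels, self.cohort)
                .rename_axis(index="cluster", columns="cohort"))


def _embed_umap(X: np.ndarray, seed: int) -> np.ndarray:
    import warnings

    import umap  # deferred: heavy import

    n_neighbors = min(15, X.shape[0] - 1)
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=seed)
    with warnings.catch_warnings():
        # seeding deliberately forces single-threaded layout
        warnings.filterwarnings("ignore", message=".*n_jobs value.*")
        return np.asarray(reducer.fit_transform(X))


def _embed_pca(X: np.ndarray, seed: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    return PCA(n_components=2, random_state=seed).fit_transform(X)


_EMBEDDINGS = {"umap": _embed_umap, "pca": _embed_pca}


def cluster_cohorts(train_table: FeatureTable, valid_table: FeatureTable,
                    features: Sequence[str], min_cluster_size: int = 8,
                    embedding_seed: int = 0, embedding: str = "umap",
                    psi_bins: int = 10) -> DriftReport:
    """Pool cohorts, listwise-delete incomplete records, embed, and cluster.

    Numerics are z-scaled and categoricals one-hot encoded on the pooled data
    before the 2-D embedding; clusters come from hierarchical density-based
    clustering (HDBSCAN) with the given minimum cluster size. The embedding
    backend is pluggable ("umap" default, "pca" for cheap deterministic runs);
    PSI never depends on it.
    """
    from sklearn.cluster import HDBSCAN
    from sklearn.preprocessing import StandardScaler

    for f in features:
        for tbl, name in ((train_table, "train"), (valid_table, "valid")):
            if f not in tbl.features:
                raise ValueError(f"feature {f!r} missing from {name} table")

    # cohorts may reuse patient ids; disambiguate in the pooled index
    tframe = train_table.frame[list(features)].copy()
    tframe.index = [f"train:{p}" for p in tframe.index]
    vframe = valid_table.frame[list(features)].copy()
    vframe.index = [f"valid:{p}" for p in vframe.index]
    pooled = pd.concat([tframe, vframe])
    cohort = pd.Series(["train"] * len(tframe) + ["valid"] * len(vframe),
                       index=pooled.index)
    complete = ~pooled.isna().any(axis=1)
    n_removed = int((~complete).sum())
    retained = pooled.loc[complete]
    if len(retained) < 2 * min_cluster_size:
        raise ValueError("too few complete records to cluster")

    blocks = []
    for f in features:
        if train_table.kinds[f] == NUMERIC:
            blocks.append(StandardScaler().fit_transform(
                retained[[f]].to_numpy(dtype=float)))
        else:
            blocks.append(pd.get_dummies(retained[f].astype(str)).to_numpy(dtype=float))
    X = np.hstack(blocks)

    emb = _EMBEDDINGS[embedding](X, embedding_seed)
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(emb)

    psi_table = feature_psi(train_table, valid_table, features, n_bins=psi_bins)
    return DriftReport(psi_table=psi_table,
                       labels=pd.Series(labels, index=retained.index, name="cluster"),
                       cohort=cohort.loc[complete],
                       data=retained,
                       embedding=emb, n_removed=n_removed,
                       features=tuple(features))


def summarize_clusters(report: DriftReport, train_table: FeatureTable,
                       valid_table: FeatureTable) -> pd.DataFrame:
    """Per-cluster feature summaries: numeric mean + t-CI, categorical
    level frequencies, and per-cohort record counts."""
    pooled = report.data
    rows = []
    for cluster in sorted(report.labels.unique()):
        members = report.labels.index[report.labels == cluster]
        cohorts = report.cohort.loc[members]
        base = {"cluster": int(cluster), "n": len(members),
                "n_train": int((cohorts == "train").sum()),
                "n_valid": int((cohorts == "valid").sum())}
        for f in report.features:
            vals = pooled.loc[members, f]
            if train_table.kinds[f] == NUMERIC:
                arr = vals.to_numpy(dtype=float)
                if arr.size >= 2:
                    mu, lo, hi = _t_ci(arr)
                else:
                    mu = float(arr[0]); lo = hi = mu
                rows.append({**base, "feature": f, "kind": "numeric",
                             "mean": mu, "ci_low": lo, "ci_high": hi,
                             "levels": None})
            else:
                freqs = vals.astype(str).value_counts(normalize=True).to_dict()
                rows.append({**base, "feature": f, "kind": "categorical",
                             "mean": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                             "levels": {k: round(float(v), 6)
                                        for k, v in sorted(freqs.items())}})
    return pd.DataFrame(rows)
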