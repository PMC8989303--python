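"""Preprocessing + estimator "blueprints" fitted per project.

A blueprint bundles a numeric encoder, a categorical encoder, and an
estimator. Fitting a blueprint under a partition plan performs k-fold
cross-validation with all preprocessing (imputation, binning, scaling,
encoding) fitted on training folds only, captures out-of-fold predictions,
and computes per-project permutation importance and the best-F1 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .core_data import CATEGORICAL, NUMERIC, FeatureTable, PartitionPlan
from .metrics_stability import CLIP, PFIList, auc, logloss, normalize_importances

NUMERIC_ENCODERS = ("quintile-spline", "passthrough-standardize")
CATEGORICAL_ENCODERS = ("one-hot", "ordinal")
ESTIMATORS = ("l2-logistic", "gradient-boosted-trees", "majority-class")

_MISSING_LEVEL = "__missing__"

_HYPERPARAMETERS = {
    "l2-logistic": {"C": 1.0, "max_iter": 1000},
    # defaults chosen for reproducibility; override per run
    "gradient-boosted-trees": {"n_estimators": 500, "learning_rate": 0.05,
                               "max_depth": 3},
    "majority-class": {},
}


@dataclass(frozen=True)
class BlueprintSpec:
    """Declarative description of one preprocessing + estimator combination."""

    name: str
    numeric_encoder: str = "passthrough-standardize"
    categorical_encoder: str = "one-hot"
    estimator: str = "l2-logistic"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    estimator_seed: int = 0

    def __post_init__(self):
        if self.numeric_encoder not in NUMERIC_ENCODERS:
            raise ValueError(f"unknown numeric encoder {self.numeric_encoder!r}")
        if self.categorical_encoder not in CATEGORICAL_ENCODERS:
            raise ValueError(f"unknown categorical encoder {self.categorical_encoder!r}")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        allowed = set(_HYPERPARAMETERS[self.estimator])
        unknown = set(self.hyperparameters) - allowed
        if unknown:
            raise ValueError(
                f"hyperparameters {sorted(unknown)} not valid for {self.estimator}")

    def resolved_hyperparameters(self) -> dict:
        out = dict(_HYPERPARAMETERS[self.estimator])
        out.update(self.hyperparameters)
        return out


def logistic_blueprint(name: str = "bp_log", seed: int = 0, **hp) -> BlueprintSpec:
    """Quintile-binned L2 logistic regression (spline-style numerics)."""
    return BlueprintSpec(name=name, numeric_encoder="quintile-spline",
                         categorical_encoder="one-hot", estimator="l2-logistic",
                         hyperparameters=hp, estimator_seed=seed)


def boosted_blueprint(name: str = "bp_gbt", seed: int = 0, **hp) -> BlueprintSpec:
    """Gradient-boosted trees with one-hot categoricals."""
    return BlueprintSpec(name=name, numeric_encoder="passthrough-standardize",
                         categorical_encoder="one-hot",
                         estimator="gradient-boosted-trees",
                         hyperparameters=hp, estimator_seed=seed)


def majority_blueprint(name: str = "bp_majority", seed: int = 0) -> BlueprintSpec:
    """Benchmark that always predicts the training-fold prevalence."""
    return BlueprintSpec(name=name, estimator="majority-class", estimator_seed=seed)


# ---------------------------------------------------------------------------
# Encoders / preprocessing
# ---------------------------------------------------------------------------

class QuintileBinEncoder:
    """One-hot quintile binning fitted on training-fold values.

    Bin edges are the training 20/40/60/80 linear-interpolation percentiles,
    deduplicated and restricted to the open interval between the training
    minimum and maximum, so columns with fewer than five distinct values
    degrade gracefully down to a single bin for constants. Out-of-range
    values clamp into the extreme bins by construction.
    """

    def fit(self, values: np.ndarray) -> "QuintileBinEncoder":
        vals = np.asarray(values, dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("all-missing numeric column")
        edges = np.percentile(vals, [20, 40, 60, 80])
        edges = np.unique(edges)
        lo, hi = vals.min(), vals.max()
        self.edges_ = edges[(edges > lo) & (edges < hi)]
        self.n_bins_ = self.edges_.size + 1
        return self

    def bin_index(self, values: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.edges_, np.asarray(values, dtype=float),
                               side="right")

    def transform(self, values: np.ndarray) -> np.ndarray:
        idx = self.bin_index(values)
        out = np.zeros((idx.size, self.n_bins_))
        out[np.arange(idx.size), idx] = 1.0
        return out


class TablePreprocessor:
    """Column-wise imputation + encoding with a feature -> column-block map.

    Numeric columns: impute training median, then quintile-bin or
    standardize. Categorical columns: missing becomes an explicit level;
    one-hot over training levels (unseen -> all-zero) or ordinal codes.
    """

    def __init__(self, kinds: Mapping[str, str], numeric_encoder: str,
                 categorical_encoder: str):
        self.kinds = dict(kinds)
        self.numeric_encoder = numeric_encoder
        self.categorical_encoder = categorical_encoder

    def fit(self, frame: pd.DataFrame) -> "TablePreprocessor":
        self.columns_ = list(frame.columns)
        self.state_: dict[str, dict] = {}
        self.blocks_: dict[str, slice] = {}
        pos = 0
        for col in self.columns_:
            if self.kinds[col] == NUMERIC:
                vals = frame[col].to_numpy(dtype=float)
                nonmiss = vals[~np.isnan(vals)]
                if nonmiss.size == 0:
                    raise ValueError(f"all-missing numeric column {col!r}")
                median = float(np.median(nonmiss))
                if self.numeric_encoder == "quintile-spline":
                    enc = QuintileBinEncoder().fit(nonmiss)
                    width = enc.n_bins_
                    self.state_[col] = {"median": median, "encoder": enc}
                else:
                    mean = float(np.mean(nonmiss))
                    sd = float(np.std(nonmiss, ddof=0)) or 1.0
                    width = 1
                    self.state_[col] = {"median": median, "mean": mean, "sd": sd}
            else:
                levels = sorted({str(v) for v in frame[col].dropna()})
                levels.append(_MISSING_LEVEL)
                if self.categorical_encoder == "one-hot":
                    width = len(levels)
                else:
                    width = 1
                self.state_[col] = {"levels": levels,
                                    "index": {l: i for i, l in enumerate(levels)}}
            self.blocks_[col] = slice(pos, pos + width)
            pos += width
        self.n_columns_ = pos
        return self

    def _transform_column(self, col: str, series: pd.Series) -> np.ndarray:
        st = self.state_[col]
        if self.kinds[col] == NUMERIC:
            vals = series.to_numpy(dtype=float)
            vals = np.where(np.isnan(vals), st["median"], vals)
            if self.numeric_encoder == "quintile-spline":
                return st["encoder"].transform(vals)
            return ((vals - st["mean"]) / st["sd"])[:, None]
        labels = [str(v) if pd.notna(v) else _MISSING_LEVEL for v in series]
        if self.categorical_encoder == "one-hot":
            out = np.zeros((len(labels), len(st["levels"])))
            for i, lab in enumerate(labels):
                j = st["index"].get(lab)
                if j is not None:
                    out[i, j] = 1.0
            return out
        codes = np.asarray([st["index"].get(lab, -1) for lab in labels], dtype=float)
        return codes[:, None]

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        out = np.empty((len(frame), self.n_columns_))
        for col in self.columns_:
            out[:, self.blocks_[col]] = self._transform_column(col, frame[col])
        return out


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _make_estimator(spec: BlueprintSpec):
    hp = spec.resolved_hyperparameters()
    if spec.estimator == "l2-logistic":
        return LogisticRegression(penalty="l2", C=float(hp["C"]),
                                  max_iter=int(hp["max_iter"]), solver="lbfgs",
                                  random_state=spec.estimator_seed)
    if spec.estimator == "gradient-boosted-trees":
        return GradientBoostingClassifier(
            n_estimators=int(hp["n_estimators"]),
            learning_rate=float(hp["learning_rate"]),
            max_depth=int(hp["max_depth"]),
            random_state=spec.estimator_seed)
    return DummyClassifier(strategy="prior", random_state=spec.estimator_seed)


def _fit_estimator(spec: BlueprintSpec, X: np.ndarray, y: np.ndarray):
    """Fit, retrying once with stronger regularization on non-convergence."""
    est = _make_estimator(spec)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(X, y)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if converged or spec.estimator != "l2-logistic":
        return est
    warnings.warn(f"{spec.name}: logistic fit did not converge; retrying with C/10")
    hp = spec.resolved_hyperparameters()
    retry = LogisticRegression(penalty="l2", C=float(hp["C"]) / 10.0,
                               max_iter=int(hp["max_iter"]) * 2, solver="lbfgs",
                               random_state=spec.estimator_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        retry.fit(X, y)
    return retry


class FittedBlueprint:
    """A preprocessor + estimator pair fitted on one training set."""

    def __init__(self, spec: BlueprintSpec, preprocessor: TablePreprocessor, estimator):
        self.spec = spec
        self.preprocessor = preprocessor
        self.estimator = estimator

    @property
    def features(self) -> list[str]:
        return list(self.preprocessor.columns_)

    @property
    def blocks(self) -> dict[str, slice]:
        return self.preprocessor.blocks_

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability from an already-transformed design."""
        est = self.estimator
        if isinstance(est, LogisticRegression):
            # bypass sklearn's per-call input validation (hot loop in pFI)
            z = X @ est.coef_[0] + est.intercept_[0]
            p = 1.0 / (1.0 + np.exp(-z))
            if est.classes_[1] != 1:  # pragma: no cover - classes_ is sorted
                p = 1.0 - p
        else:
            pos = list(est.classes_).index(1)
            p = est.predict_proba(X)[:, pos]
        return np.clip(p, CLIP, 1.0 - CLIP)

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        """Positive-class probability for raw predictor rows."""
        return self.predict_proba_matrix(self.preprocessor.transform(frame))


def fit_model(spec: BlueprintSpec, frame: pd.DataFrame, y: np.ndarray,
              kinds: Mapping[str, str]) -> FittedBlueprint:
    pre = TablePreprocessor(kinds, spec.numeric_encoder,
                            spec.categorical_encoder).fit(frame)
    est = _fit_estimator(spec, pre.transform(frame), y)
    return FittedBlueprint(spec, pre, est)


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

def best_f1_threshold(targets: Sequence[int], probabilities: Sequence[float]) -> float:
    """Probability threshold maximizing F1 of the positive class.

    Candidates are 0, 1, and the midpoints between consecutive sorted unique
    probabilities; a record is predicted positive when its probability is
    strictly above the threshold. Ties break toward the lower threshold.
    """
    y = np.asarray(targets, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if not np.any(y == 1):
        raise ValueError("no positive targets; F1 threshold undefined")
    uniq = np.unique(p)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    best_t, best_f1 = 0.0, -1.0
    for t in candidates:
        pred = p > t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


# ---------------------------------------------------------------------------
# Project fitting
# ---------------------------------------------------------------------------

@dataclass
class ProjectResult:
    """Cross-validated outputs of one blueprint under one partition plan."""

    blueprint: str
    project_seed: int
    fold_logloss: tuple[float, ...]
    fold_auc: tuple[float, ...]
    cv_logloss: float
    cv_auc: float
    oof_predictions: pd.Series
    pfi: PFIList | None
    best_f1_threshold: float
    model: FittedBlueprint | None = None  # full-data refit; not serialized
    fold_models: tuple[FittedBlueprint, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "blueprint": self.blueprint,
            "project_seed": int(self.project_seed),
            "fold_logloss": [float(v) for v in self.fold_logloss],
            "fold_auc": [float(v) for v in self.fold_auc],
            "cv_logloss": float(self.cv_logloss),
            "cv_auc": float(self.cv_auc),
            "best_f1_threshold": float(self.best_f1_threshold),
            "pfi": None if self.pfi is None else {
                "features": list(self.pfi.features),
                "importances": [float(v) for v in self.pfi.importances],
            },
        }


def fit_blueprint(spec: BlueprintSpec, table: FeatureTable, plan: PartitionPlan,
                  compute_pfi: bool = True, n_permutations: int = 10,
                  refit_full: bool = True,
                  keep_fold_models: bool = False) -> ProjectResult:
    """Run one project: k-fold CV with out-of-fold capture.

    Preprocessing and the estimator are fitted on the k-1 training folds only;
    permutation importance is computed on each held-out fold and averaged
    within the project before normalization. Deterministic given
    ``(spec, table, plan)``.
    """
    from . import explain  # local import: explain consumes fitted blueprints

    y = table.y
    folds = plan.folds(table.patients)
    oof = np.full(table.n_patients, np.nan)
    fold_ll, fold_auc_ = [], []
    fold_models = []
    raw_pfi = np.zeros(len(table.features)) if compute_pfi else None

    for j in range(plan.k):
        test = folds == j
        train = ~test
        model = fit_model(spec, table.frame.loc[train], y[train], table.kinds)
        if keep_fold_models:
            fold_models.append(model)
        p = model.predict_proba(table.frame.loc[test])
        oof[test] = p
        fold_ll.append(logloss(y[test], p))
        fold_auc_.append(auc(y[test], p))
        if compute_pfi:
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.estimator_seed, plan.seed & 0xFFFFFFFF, j]))
            raw = explain.raw_permutation_importance(
                model, table.frame.loc[test], y[test],
                n_permutations=n_permutations, rng=rng)
            raw_pfi += raw / plan.k

    pfi = None
    if compute_pfi:
        pfi = normalize_importances(table.features, raw_pfi)

    result = ProjectResult(
        blueprint=spec.name,
        project_seed=plan.seed,
        fold_logloss=tuple(fold_ll),
        fold_auc=tuple(fold_auc_),
        cv_logloss=logloss(y, oof),
        cv_auc=auc(y, oof),
        oof_predictions=pd.Series(oof, index=table.patients, name="oof"),
        pfi=pfi,
        best_f1_threshold=best_f1_threshold(y, oof),
        model=fit_model(spec, table.frame, y, table.kinds) if refit_full else None,
        fold_models=tuple(fold_models) if keep_fold_models else None,
    )
    return result


def fit_projects(spec: BlueprintSpec, table: FeatureTable, projects,
                 **kwargs) -> list[ProjectResult]:
    """Fit one blueprint under every plan of a project set."""
    return [fit_blueprint(spec, table, plan, **kwargs) for plan in projects]
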