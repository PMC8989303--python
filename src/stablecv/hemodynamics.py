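"""Intraoperative vitals features and the MAP threshold sweep.

Raw per-patient timeseries (HR, SysBP, DiaBP, MAP) are reduced to
distributional summaries (mean, sd, skew, kurtosis) and to the total time
spent strictly above an upper / strictly below a lower mean-arterial-pressure
threshold. The sweep refits a blueprint across all projects for every
candidate single-threshold feature to locate the most predictive threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .blueprints import BlueprintSpec, fit_blueprint
from .core_data import NUMERIC, FeatureTable, ProjectSet
from .metrics_stability import AggregateResult, aggregate

SIGNALS = ("HR", "SysBP", "DiaBP", "MAP")
SUMMARY_STATS = ("mean", "sd", "skew", "kurtosis")

DEFAULT_LOWER = 76
DEFAULT_UPPER = 104
LOWER_RANGE = range(70, 86)   # 16 candidate lower thresholds
UPPER_RANGE = range(95, 116)  # 21 candidate upper thresholds


@dataclass(frozen=True)
class VitalsTimeseries:
    """One patient's samples for one signal, in minutes from surgery start."""

    patient_id: object
    signal: str
    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if self.signal not in SIGNALS:
            raise ValueError(f"unknown signal {self.signal!r}")
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValueError("times and values must align")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if v.size and (not np.all(np.isfinite(v)) or np.any(v <= 0)):
            raise ValueError("values must be finite and positive")


class VitalsCollection:
    """All series for a cohort, keyed by (patient_id, signal)."""

    def __init__(self, series: Iterable[VitalsTimeseries] = ()):
        self._series: dict[tuple, VitalsTimeseries] = {}
        for s in series:
            self.add(s)

    def add(self, series: VitalsTimeseries) -> None:
        key = (series.patient_id, series.signal)
        if key in self._series:
            raise ValueError(f"duplicate series for {key}")
        self._series[key] = series

    def get(self, patient_id, signal: str) -> VitalsTimeseries | None:
        return self._series.get((patient_id, signal))

    def patients(self) -> list:
        return sorted({p for p, _ in self._series}, key=str)

    def __len__(self) -> int:
        return len(self._series)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pid, sig), s in sorted(self._series.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
            for t, v in zip(s.times, s.values):
                rows.append((pid, sig, t, v))
        return pd.DataFrame(rows, columns=["patient_id", "signal", "time_min", "value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VitalsCollection":
        coll = cls()
        for (pid, sig), grp in frame.groupby(["patient_id", "signal"], sort=True):
            grp = grp.sort_values("time_min")
            coll.add(VitalsTimeseries(patient_id=pid, signal=sig,
                                      times=tuple(grp["time_min"].tolist()),
                                      values=tuple(grp["value"].tolist())))
        return coll

    @classmethod
    def from_csv(cls, path: str | Path) -> "VitalsCollection":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def summarize_signal(series: VitalsTimeseries) -> tuple[float, float, float, float]:
    """(mean, sd, skew, excess kurtosis) of the sampled values, ignoring timing.

    sd uses the n-1 denominator; skew and kurtosis are the bias-uncorrected
    Fisher-Pearson forms. Moments whose sample-size preconditions are not met
    (or that would divide by a zero sd) come back as NaN rather than raising.
    """
    v = np.asarray(series.values, dtype=float)
    n = v.size
    mean = float(np.mean(v)) if n else np.nan
    sd = float(np.std(v, ddof=1)) if n >= 2 else np.nan
    dev = v - mean
    m2 = float(np.mean(dev ** 2)) if n else np.nan
    skew = kurt = np.nan
    if n >= 3 and m2 > 0:
        skew = float(np.mean(dev ** 3)) / m2 ** 1.5
    if n >= 4 and m2 > 0:
        kurt = float(np.mean(dev ** 4)) / m2 ** 2 - 3.0
    return mean, sd, skew, kurt


def _interval_widths(times: np.ndarray) -> np.ndarray:
    """Per-sample owned interval: gap to the successor; the last sample owns
    the median sampling interval (0 for a single-sample series)."""
    if times.size == 1:
        return np.asarray([0.0])
    gaps = np.diff(times)
    return np.append(gaps, np.median(gaps))


def time_outside_threshold(series: VitalsTimeseries, threshold: float,
                           direction: str) -> float:
    """Minutes a MAP series spends strictly beyond a threshold.

    Equality at the threshold counts as inside range.
    """
    if series.signal != "MAP":
        raise ValueError("threshold features are defined on the MAP signal")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    t = np.asarray(series.times, dtype=float)
    v = np.asarray(series.values, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    widths = _interval_widths(t)
    mask = v > threshold if direction == "above" else v < threshold
    return float(np.sum(widths[mask]))


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

def summary_feature_names() -> list[str]:
    return [f"{sig}_{stat}" for sig in SIGNALS for stat in SUMMARY_STATS]


def threshold_feature_names(lower: float = DEFAULT_LOWER,
                            upper: float = DEFAULT_UPPER) -> tuple[str, str]:
    return (f"time_MAP_Avg_above_{upper:g}", f"time_MAP_Avg_below_{lower:g}")


def is_threshold_feature(name: str) -> bool:
    return name.startswith("time_MAP_Avg_above_") or name.startswith("time_MAP_Avg_below_")


def build_summary_features(table: FeatureTable, vitals: VitalsCollection) -> FeatureTable:
    """Append mean/sd/skew/kurtosis columns for each of the four signals."""
    cols = {}
    for sig in SIGNALS:
        per_stat = {stat: [] for stat in SUMMARY_STATS}
        for pid in table.patients:
            series = vitals.get(pid, sig)
            stats_ = summarize_signal(series) if series else (np.nan,) * 4
            for stat, val in zip(SUMMARY_STATS, stats_):
                per_stat[stat].append(val)
        for stat in SUMMARY_STATS:
            cols[f"{sig}_{stat}"] = per_stat[stat]
    new = pd.DataFrame(cols, index=table.patients)
    return table.with_columns(new, {c: NUMERIC for c in new.columns})


def build_threshold_features(table: FeatureTable, vitals: VitalsCollection,
                             lower: float = DEFAULT_LOWER,
                             upper: float = DEFAULT_UPPER) -> FeatureTable:
    """Append the two time-outside-threshold columns (missing series -> NaN)."""
    above_name, below_name = threshold_feature_names(lower, upper)
    above, below = [], []
    for pid in table.patients:
        series = vitals.get(pid, "MAP")
        if series is None:
            above.append(np.nan)
            below.append(np.nan)
        else:
            above.append(time_outside_threshold(series, upper, "above"))
            below.append(time_outside_threshold(series, lower, "below"))
    new = pd.DataFrame({above_name: above, below_name: below}, index=table.patients)
    return table.with_columns(new, {above_name: NUMERIC, below_name: NUMERIC})


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepEntry:
    side: str                    # "baseline" | "lower" | "upper"
    threshold: float | None
    logloss: AggregateResult
    auc: AggregateResult


@dataclass(frozen=True)
class SweepResult:
    entries: tuple[SweepEntry, ...]

    def best(self, side: str) -> SweepEntry:
        """Entry with minimal mean LogLoss on one side of the sweep."""
        pool = [e for e in self.entries if e.side == side]
        return min(pool, key=lambda e: (e.logloss.mean, e.threshold or 0))

    def baseline(self) -> SweepEntry:
        return next(e for e in self.entries if e.side == "baseline")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"side": e.side, "threshold_mmHg": e.threshold,
                 "mean_logloss": e.logloss.mean,
                 "logloss_ci_low": e.logloss.ci_low,
                 "logloss_ci_high": e.logloss.ci_high,
                 "mean_auc": e.auc.mean,
                 "auc_ci_low": e.auc.ci_low,
                 "auc_ci_high": e.auc.ci_high} for e in self.entries]
        return pd.DataFrame(rows)


def threshold_sweep(blueprint: BlueprintSpec, base_features: Sequence[str],
                    table: FeatureTable, vitals: VitalsCollection,
                    projects: ProjectSet,
                    lower_range: Iterable[float] = LOWER_RANGE,
                    upper_range: Iterable[float] = UPPER_RANGE) -> SweepResult:
    """Refit the blueprint across all projects for every single-threshold
    feature list plus the no-threshold baseline.

    All conditions share the same partition plans, so performance differences
    are attributable to the candidate feature alone.
    """
    lowers = list(lower_range)
    uppers = list(upper_range)
    if not lowers and not uppers:
        raise ValueError("empty threshold ranges")
    bad = [f for f in base_features if is_threshold_feature(f)]
    if bad:
        raise ValueError(f"base_features must exclude threshold features: {bad}")

    def run(features: Sequence[str], work: FeatureTable,
            side: str, threshold: float | None) -> SweepEntry:
        sub = work.select(list(features))
        results = [fit_blueprint(blueprint, sub, plan, compute_pfi=False,
                                 refit_full=False) for plan in projects]
        return SweepEntry(
            side=side, threshold=threshold,
            logloss=aggregate([r.cv_logloss for r in results], "cv_logloss"),
            auc=aggregate([r.cv_auc for r in results], "cv_auc"))

    entries = [run(base_features, table, "baseline", None)]
    for lo in lowers:
        work = build_threshold_features(table, vitals, lower=lo, upper=DEFAULT_UPPER)
        _, below_name = threshold_feature_names(lower=lo)
        entries.append(run([*base_features, below_name], work, "lower", float(lo)))
    for up in uppers:
        work = build_threshold_features(table, vitals, lower=DEFAULT_LOWER, upper=up)
        above_name, _ = threshold_feature_names(upper=up)
        entries.append(run([*base_features, above_name], work, "upper", float(up)))
    return SweepResult(entries=tuple(entries))
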