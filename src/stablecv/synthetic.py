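"""Seeded generators for SCI-like synthetic cohorts.

Produces per-patient intraoperative vitals traces (first-order autoregressive
with random excursion episodes beyond the MAP thresholds), tabular covariates,
and a binary outcome drawn from a logistic model on the true feature values.
A drifted-cohort generator shifts the configured distributions to emulate an
external validation population. Everything is fully determined by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import CATEGORICAL, NUMERIC, AIS_GRADES, FeatureTable
from .hemodynamics import (SIGNALS, VitalsCollection, VitalsTimeseries,
                           build_summary_features, build_threshold_features,
                           threshold_feature_names)


@dataclass(frozen=True)
class SignalConfig:
    baseline_mean: float
    baseline_sd: float
    ar_coef: float = 0.9


DEFAULT_SIGNALS: dict[str, SignalConfig] = {
    "HR": SignalConfig(78.0, 6.0),
    "SysBP": SignalConfig(122.0, 9.0),
    "DiaBP": SignalConfig(68.0, 6.0),
    "MAP": SignalConfig(90.0, 6.0),
}

#: Log-odds coefficients applied to z-scored true feature values.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "time_above_upper": -0.9,
    "time_below_lower": -0.6,
    "MRI_1_BASIC_Score": -0.8,
    "AIS_ad": 0.5,
    "Cervical_Injury": -0.3,
    "TBI_Present": -0.25,
    "Vertebral_Artery_Injury": -0.2,
    "Time_to_OR": -0.4,
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters for one synthetic cohort.

    The default shape mirrors a small SCI training cohort: 74 patients,
    46 predictors (18 timeseries-derived including the two MAP threshold
    features), and a ~53% improvement prevalence.
    """

    n_patients: int = 74
    prevalence: float = 39 / 74
    seed: int = 0
    sampling_interval: float = 1.0
    duration_range: tuple[int, int] = (180, 300)
    signals: Mapping[str, SignalConfig] = field(
        default_factory=lambda: dict(DEFAULT_SIGNALS))
    lower_threshold: float = 76.0
    upper_threshold: float = 104.0
    above_episode_rate: float = 0.9    # Poisson mean episodes per patient
    below_episode_rate: float = 0.9
    episode_duration_mean: float = 35.0  # minutes, exponential
    episode_shift_scale: float = 5.0     # mmHg beyond threshold, exponential
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    n_noise: int = 22
    missingness_rate: float = 0.02
    time_to_or_mean_hours: float = 80.0
    time_to_or_log_sd: float = 0.5
    binary_rates: Mapping[str, float] = field(default_factory=lambda: {
        "Cervical_Injury": 0.55, "TBI_Present": 0.30,
        "Vertebral_Artery_Injury": 0.15})
    ais_probs: tuple[float, ...] = (0.30, 0.20, 0.20, 0.25, 0.05)
    basic_probs: tuple[float, ...] = (0.10, 0.20, 0.30, 0.25, 0.15)

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.duration_range[0] <= 0:
            raise ValueError("durations must be positive")
        for v in self.coefficients.values():
            if not math.isfinite(v):
                raise ValueError("coefficients must be finite")


@dataclass(frozen=True)
class DriftSpec:
    """Distribution shifts applied to a base config for a validation cohort."""

    n_patients: int = 59
    prevalence: float = 14 / 59
    time_to_or_scale: float = 1.0      # multiplies Time_to_OR location
    below_episode_scale: float = 1.0   # multiplies hypotension episode rate
    above_episode_scale: float = 1.0
    binary_rates: Mapping[str, float] = field(default_factory=dict)
    seed_offset: int = 104729          # large prime; decorrelates the cohorts

    def __post_init__(self):
        if self.time_to_or_scale <= 0:
            raise ValueError("scale multipliers must be positive")
        for p in self.binary_rates.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("binary rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Trace generation
# ---------------------------------------------------------------------------

def _episodes(n: int, rate: float, duration_mean: float, interval: float,
              taken: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    """Random-onset, random-duration episodes as per-episode sample-index
    arrays, avoiding already-occupied samples."""
    out = []
    occupied = taken.copy()
    for _ in range(rng.poisson(rate)):
        length = max(1, int(round(rng.exponential(duration_mean) / interval)))
        start = int(rng.integers(0, max(1, n - length)))
        idx = np.arange(start, min(n, start + length))
        idx = idx[~occupied[idx]]
        if idx.size:
            occupied[idx] = True
            out.append(idx)
    return out


def _ar_trace(n: int, cfg: SignalConfig, rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfilter

    innov_sd = cfg.baseline_sd * math.sqrt(max(1.0 - cfg.ar_coef ** 2, 1e-6))
    initial_dev = rng.normal(0, cfg.baseline_sd)
    noise = rng.normal(0, innov_sd, size=n)
    # y[t] = u[t] + ar * y[t-1] with u[0] seeding the stationary start
    u = np.concatenate(([initial_dev], noise[1:]))
    dev = lfilter([1.0], [1.0, -cfg.ar_coef], u)
    return cfg.baseline_mean + dev


def _simulate_map_trace(n: int, config: CohortConfig, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MAP values plus boolean above/below-episode masks.

    Baseline samples are clipped strictly inside the thresholds; episode
    samples are pushed strictly beyond, so the generator's excursion
    bookkeeping and trace-derived time-outside agree exactly. Excursion depth
    is drawn per episode (patients differ in how far beyond the threshold
    they stray), with small within-episode jitter.
    """
    lo, hi = config.lower_threshold, config.upper_threshold
    base = np.clip(_ar_trace(n, config.signals["MAP"], rng), lo + 0.5, hi - 0.5)
    above_eps = _episodes(n, config.above_episode_rate,
                          config.episode_duration_mean,
                          config.sampling_interval, np.zeros(n, bool), rng)
    above = np.zeros(n, dtype=bool)
    for idx in above_eps:
        above[idx] = True
    below_eps = _episodes(n, config.below_episode_rate,
                          config.episode_duration_mean,
                          config.sampling_interval, above, rng)
    below = np.zeros(n, dtype=bool)
    for idx in below_eps:
        below[idx] = True

    values = base.copy()
    for idx in above_eps:
        depth = 1.0 + rng.exponential(config.episode_shift_scale)
        jitter = rng.normal(0, 0.3, size=idx.size)
        values[idx] = np.maximum(hi + depth + jitter, hi + 0.5)
    for idx in below_eps:
        depth = 1.0 + rng.exponential(config.episode_shift_scale)
        jitter = rng.normal(0, 0.3, size=idx.size)
        values[idx] = np.clip(lo - depth + jitter, 5.0, lo - 0.5)
    return values, above, below


# ---------------------------------------------------------------------------
# Outcome model
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v)
    return (v - np.mean(v)) / sd if sd > 0 else np.zeros_like(v)


def calibrate_intercept(linear: np.ndarray, prevalence: float,
                        lo: float = -30.0, hi: float = 30.0) -> float:
    """Bisect the intercept so mean sigmoid(intercept + linear) = prevalence."""

    def mean_p(b: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b + linear)))))

    if not (mean_p(lo) <= prevalence <= mean_p(hi)):
        raise ValueError("target prevalence infeasible for given coefficients")
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if mean_p(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig
                    ) -> tuple[FeatureTable, VitalsCollection, dict]:
    """Generate one labeled cohort: feature table, vitals, and ground truth.

    The outcome is drawn from a logistic model on the *true* (pre-missingness)
    feature values; noise features are independent of everything.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"P{i:04d}" for i in range(n)]
    dt = config.sampling_interval

    vitals = VitalsCollection()
    true_above = np.zeros(n)
    true_below = np.zeros(n)
    for i, pid in enumerate(ids):
        n_samples = int(rng.integers(config.duration_range[0],
                                     config.duration_range[1] + 1))
        times = tuple(np.arange(n_samples) * dt)
        for sig in SIGNALS:
            if sig == "MAP":
                values, above, below = _simulate_map_trace(n_samples, config, rng)
                true_above[i] = above.sum() * dt
                true_below[i] = below.sum() * dt
            else:
                values = np.maximum(_ar_trace(n_samples, config.signals[sig], rng), 1.0)
            vitals.add(VitalsTimeseries(patient_id=pid, signal=sig,
                                        times=times, values=tuple(values)))

    ais_idx = rng.choice(len(AIS_GRADES), size=n, p=config.ais_probs)
    basic = rng.choice(5, size=n, p=config.basic_probs).astype(float)
    binaries = {name: (rng.random(n) < p).astype(int)
                for name, p in config.binary_rates.items()}
    time_to_or = rng.lognormal(math.log(config.time_to_or_mean_hours),
                               config.time_to_or_log_sd, size=n)
    noise = rng.normal(0, 1, size=(n, config.n_noise))

    # outcome on true values
    truth_vectors = {
        "time_above_upper": true_above,
        "time_below_lower": true_below,
        "MRI_1_BASIC_Score": basic,
        "AIS_ad": ais_idx.astype(float),
        "Time_to_OR": np.log(time_to_or),
        **{name: vals.astype(float) for name, vals in binaries.items()},
    }
    linear = np.zeros(n)
    for name, coef in config.coefficients.items():
        if name not in truth_vectors:
            raise ValueError(f"coefficient on unknown feature {name!r}")
        linear += coef * _zscore(truth_vectors[name])
    intercept = calibrate_intercept(linear, config.prevalence)
    probs = 1.0 / (1.0 + np.exp(-(intercept + linear)))
    y = (rng.random(n) < probs).astype(int)

    frame = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
    frame["AIS_ad"] = [AIS_GRADES[j] for j in ais_idx]
    frame["MRI_1_BASIC_Score"] = basic
    for name, vals in binaries.items():
        # string levels survive CSV round-trips unchanged
        frame[name] = np.where(vals == 1, "yes", "no")
    frame["Time_to_OR"] = time_to_or
    for j in range(config.n_noise):
        frame[f"noise_{j + 1:02d}"] = noise[:, j]

    kinds = {"AIS_ad": CATEGORICAL, "MRI_1_BASIC_Score": NUMERIC,
             "Time_to_OR": NUMERIC}
    kinds.update({name: CATEGORICAL for name in binaries})
    kinds.update({f"noise_{j + 1:02d}": NUMERIC for j in range(config.n_noise)})

    table = FeatureTable(frame=frame, kinds=kinds,
                         target=pd.Series(y, index=frame.index, name="target"))
    table = build_summary_features(table, vitals)
    table = build_threshold_features(table, vitals,
                                     lower=config.lower_threshold,
                                     upper=config.upper_threshold)

    if config.missingness_rate > 0:
        mask = rng.random(table.frame.shape) < config.missingness_rate
        # never blank a full column
        for j, col in enumerate(table.frame.columns):
            if mask[:, j].all():
                mask[0, j] = False
            table.frame.loc[mask[:, j], col] = np.nan

    above_name, below_name = threshold_feature_names(
        config.lower_threshold, config.upper_threshold)
    truth = {
        "intercept": intercept,
        "coefficients": dict(config.coefficients),
        "probabilities": probs.tolist(),
        "time_above_upper": true_above.tolist(),
        "time_below_lower": true_below.tolist(),
        "threshold_features": [above_name, below_name],
        "signal_features": sorted(set(config.coefficients) & set(truth_vectors)),
        "noise_features": [f"noise_{j + 1:02d}" for j in range(config.n_noise)],
    }
    return table, vitals, truth


def simulate_drifted_cohort(config: CohortConfig, drift: DriftSpec
                            ) -> tuple[FeatureTable, VitalsCollection, dict]:
    """Generate a validation-like cohort from shifted distributions.

    The outcome model (coefficients) is unchanged; the intercept is
    recalibrated to the drifted prevalence.
    """
    shifted = replace(
        config,
        n_patients=drift.n_patients,
        prevalence=drift.prevalence,
        seed=config.seed + drift.seed_offset,
        time_to_or_mean_hours=config.time_to_or_mean_hours * drift.time_to_or_scale,
        below_episode_rate=config.below_episode_rate * drift.below_episode_scale,
        above_episode_rate=config.above_episode_rate * drift.above_episode_scale,
        binary_rates={**config.binary_rates, **drift.binary_rates},
    )
    return simulate_cohort(shifted)


# ---------------------------------------------------------------------------
# Lightweight tabular generator for recovery experiments
# ---------------------------------------------------------------------------

def simulate_signal_noise_table(n_patients: int, n_signal: int = 5,
                                n_noise: int = 15, coef: float = 1.0,
                                prevalence: float = 0.5, seed: int = 0
                                ) -> tuple[FeatureTable, dict]:
    """Purely tabular cohort: standard-normal predictors of which the first
    ``n_signal`` carry equal logistic signal and the rest are null."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(n_patients, n_signal + n_noise))
    linear = coef * X[:, :n_signal].sum(axis=1)
    intercept = calibrate_intercept(linear, prevalence)
    probs = 1.0 / (1.0 + np.exp(-(intercept + linear)))
    y = (rng.random(n_patients) < probs).astype(int)

    signal_names = [f"signal_{j + 1:02d}" for j in range(n_signal)]
    noise_names = [f"noise_{j + 1:02d}" for j in range(n_noise)]
    frame = pd.DataFrame(X, columns=signal_names + noise_names,
                         index=pd.Index([f"P{i:04d}" for i in range(n_patients)],
                                        name="patient_id"))
    table = FeatureTable(frame=frame,
                         kinds={c: NUMERIC for c in frame.columns},
                         target=pd.Series(y, index=frame.index, name="target"))
    truth = {"signal_features": signal_names, "noise_features": noise_names,
             "intercept": intercept, "coef": coef,
             "probabilities": probs.tolist()}
    return table, truth
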