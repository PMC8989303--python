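"""Backward feature elimination stabilized by cross-project pFI aggregation.

Phase 1 removes the five lowest mean-importance unprotected features per step
until five or fewer unprotected features remain; phase 2 re-runs elimination
one feature at a time inside the size window around the phase-1 optimum.
Expert-protected features are never eliminated: when one falls in the
elimination range, the next lowest-importance unprotected feature is taken
instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .blueprints import BlueprintSpec, fit_projects
from .core_data import FeatureTable, ProjectSet
from .explain import aggregate_pfi
from .metrics_stability import (AggregateResult, PFIList, aggregate, fri,
                                rank_importances)

PHASE1_STEP = 5
PHASE2_HALF_WINDOW = 5


@dataclass(frozen=True)
class ReductionStep:
    phase: int                 # 1 or 2
    features: tuple[str, ...]
    eliminated: tuple[str, ...]
    step_size: int
    logloss: AggregateResult
    auc: AggregateResult
    pfi: PFIList


@dataclass(frozen=True)
class ReductionTrace:
    steps: tuple[ReductionStep, ...]
    protected: tuple[str, ...]

    def phase_steps(self, phase: int) -> list[ReductionStep]:
        return [s for s in self.steps if s.phase == phase]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        fri_values = reduction_step_fri(self) if len(self.steps) >= 2 else []
        for i, s in enumerate(self.steps):
            rows.append({
                "step": i, "phase": s.phase, "n_features": len(s.features),
                "step_size": s.step_size,
                "mean_logloss": s.logloss.mean,
                "logloss_ci_low": s.logloss.ci_low,
                "logloss_ci_high": s.logloss.ci_high,
                "mean_auc": s.auc.mean,
                "auc_ci_low": s.auc.ci_low,
                "auc_ci_high": s.auc.ci_high,
                "fri_vs_previous": fri_values[i - 1] if i >= 1 else np.nan,
            })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "protected": list(self.protected),
            "steps": [{
                "phase": s.phase,
                "features": list(s.features),
                "eliminated": list(s.eliminated),
                "step_size": s.step_size,
                "mean_logloss": s.logloss.mean,
                "mean_auc": s.auc.mean,
                "pfi": {"features": list(s.pfi.features),
                        "importances": [float(v) for v in s.pfi.importances]},
            } for s in self.steps],
        }
        return json.dumps(payload, sort_keys=True)


def _lowest_unprotected(pfi: PFIList, protected: frozenset, n_remove: int) -> list[str]:
    """The n_remove lowest-importance unprotected features; protected features
    in the elimination range are skipped in favor of the next lowest."""
    ordered = sorted(zip(pfi.features, pfi.importances),
                     key=lambda fv: (-fv[1], fv[0]))  # best first
    worst_first = [f for f, _ in reversed(ordered)]
    out = []
    for f in worst_first:
        if f in protected:
            continue
        out.append(f)
        if len(out) == n_remove:
            break
    return out


def _evaluate(spec: BlueprintSpec, table: FeatureTable, projects: ProjectSet,
              features: Sequence[str], n_permutations: int
              ) -> tuple[AggregateResult, AggregateResult, PFIList]:
    sub = table.select(list(features))
    results = fit_projects(spec, sub, projects, compute_pfi=True,
                           n_permutations=n_permutations, refit_full=False)
    ll = aggregate([r.cv_logloss for r in results], "cv_logloss")
    au = aggregate([r.cv_auc for r in results], "cv_auc")
    return ll, au, aggregate_pfi([r.pfi for r in results])


def backward_reduce(blueprint: BlueprintSpec, table: FeatureTable,
                    projects: ProjectSet,
                    protected: Sequence[str] = (),
                    n_permutations: int = 10,
                    half_window: int = PHASE2_HALF_WINDOW) -> ReductionTrace:
    """Run the full two-phase backward elimination and record every step."""
    protected_set = frozenset(protected)
    unknown = protected_set - set(table.features)
    if unknown:
        raise ValueError(f"protected features not in table: {sorted(unknown)}")
    if protected_set >= set(table.features):
        raise ValueError("cannot reduce: all features are protected")

    steps: list[ReductionStep] = []
    features = list(table.features)

    # phase 1: step size 5
    while True:
        ll, au, pfi = _evaluate(blueprint, table, projects, features, n_permutations)
        n_unprotected = len([f for f in features if f not in protected_set])
        if n_unprotected <= PHASE1_STEP:
            eliminated: tuple[str, ...] = ()
            steps.append(ReductionStep(1, tuple(features), eliminated,
                                       PHASE1_STEP, ll, au, pfi))
            break
        drop = _lowest_unprotected(pfi, protected_set, PHASE1_STEP)
        steps.append(ReductionStep(1, tuple(features), tuple(drop),
                                   PHASE1_STEP, ll, au, pfi))
        features = [f for f in features if f not in set(drop)]

    # phase 2: step size 1 inside the window around the phase-1 optimum
    phase1 = [s for s in steps if s.phase == 1]
    best = min(phase1, key=lambda s: (s.logloss.mean, len(s.features)))
    lo = max(len(protected_set) + 1, len(best.features) - half_window)
    hi = min(len(table.features), len(best.features) + half_window)

    # restart from the recorded phase-1 list just large enough to cover hi
    covering = [s for s in phase1 if len(s.features) >= hi]
    start = min(covering, key=lambda s: len(s.features))
    features = list(start.features)
    while len(features) > hi:
        _, _, pfi = _evaluate(blueprint, table, projects, features, n_permutations)
        drop = _lowest_unprotected(pfi, protected_set, 1)
        features = [f for f in features if f not in set(drop)]

    while True:
        ll, au, pfi = _evaluate(blueprint, table, projects, features, n_permutations)
        if len(features) <= lo:
            steps.append(ReductionStep(2, tuple(features), (), 1, ll, au, pfi))
            break
        drop = _lowest_unprotected(pfi, protected_set, 1)
        steps.append(ReductionStep(2, tuple(features), tuple(drop), 1, ll, au, pfi))
        features = [f for f in features if f not in set(drop)]

    return ReductionTrace(steps=tuple(steps), protected=tuple(sorted(protected_set)))


def select_parsimonious(trace: ReductionTrace) -> tuple[tuple[str, ...], AggregateResult]:
    """Feature list with minimal aggregated mean LogLoss; ties break toward
    fewer features."""
    if not trace.steps:
        raise ValueError("empty reduction trace")
    best = min(trace.steps, key=lambda s: (s.logloss.mean, len(s.features)))
    return best.features, best.logloss


def reduction_step_fri(trace: ReductionTrace) -> list[float]:
    """FRI over surviving features for each consecutive pair of steps.

    At each transition the surviving features are re-ranked within both the
    before- and after-elimination pFI lists and compared.
    """
    if len(trace.steps) < 2:
        raise ValueError("need at least 2 steps")
    out = []
    for before, after in zip(trace.steps, trace.steps[1:]):
        shared = [f for f in after.features if f in set(before.features)]
        out.append(fri(before.pfi.restricted(shared), after.pfi.restricted(shared)))
    return out
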