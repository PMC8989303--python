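"""Patient-level data model, file I/O, target derivation, and partitioning.

The central objects are :class:`FeatureTable` (a typed patient-by-feature
table with a binary outcome), :class:`PartitionPlan` (one grouped, stratified
k-fold assignment), and :class:`ProjectSet` (a family of plans with distinct
seeds, one per repeated cross-validation "project").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NUMERIC = "numeric"
CATEGORICAL = "categorical"
_KINDS = (NUMERIC, CATEGORICAL)

#: Ordinal impairment grades, worst to best.
AIS_GRADES = ("A", "B", "C", "D", "E")


class SchemaError(ValueError):
    """Raised when a feature table violates its declared schema."""


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Predictors plus an optional binary target, indexed by patient id.

    Parameters
    ----------
    frame:
        Predictor columns only, index = unique patient ids.
    kinds:
        Mapping column name -> ``"numeric"`` | ``"categorical"``; must cover
        exactly the columns of ``frame``.
    target:
        Binary outcome aligned to ``frame.index`` (0 = not improved,
        1 = improved), or ``None`` for unlabeled tables.
    """

    frame: pd.DataFrame
    kinds: dict[str, str]
    target: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise SchemaError("patient ids must be unique")
        missing = set(self.frame.columns) - set(self.kinds)
        extra = set(self.kinds) - set(self.frame.columns)
        if missing or extra:
            raise SchemaError(
                f"kinds must cover exactly the predictor columns "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for col, kind in self.kinds.items():
            if kind not in _KINDS:
                raise SchemaError(f"unknown kind {kind!r} for column {col!r}")
            if kind == NUMERIC:
                # raises if not parseable as real numbers
                self.frame[col] = pd.to_numeric(self.frame[col])
        if self.target is not None:
            self.target = self.target.reindex(self.frame.index)
            vals = set(self.target.dropna().unique().tolist())
            if not vals <= {0, 1}:
                raise SchemaError(f"non-binary target: values {sorted(vals)}")
            if self.target.isna().any():
                raise SchemaError("target contains missing values")
            self.target = self.target.astype(int)

    # -- basic accessors ----------------------------------------------------

    @property
    def patients(self) -> pd.Index:
        return self.frame.index

    @property
    def features(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_patients(self) -> int:
        return len(self.frame)

    @property
    def y(self) -> np.ndarray:
        if self.target is None:
            raise SchemaError("table has no target")
        return self.target.to_numpy()

    def select(self, features: Sequence[str]) -> "FeatureTable":
        """Restrict to a feature subset (order preserved from `features`)."""
        unknown = [f for f in features if f not in self.kinds]
        if unknown:
            raise SchemaError(f"unknown features: {unknown}")
        return FeatureTable(
            frame=self.frame[list(features)].copy(),
            kinds={f: self.kinds[f] for f in features},
            target=None if self.target is None else self.target.copy(),
        )

    def with_columns(self, new: pd.DataFrame, kinds: Mapping[str, str]) -> "FeatureTable":
        """Return a copy with additional (or replaced) predictor columns."""
        frame = self.frame.copy()
        for col in new.columns:
            frame[col] = new[col].reindex(frame.index)
        merged = dict(self.kinds)
        merged.update(kinds)
        return FeatureTable(frame=frame, kinds=merged,
                            target=None if self.target is None else self.target.copy())


def load_feature_table(path: str | Path, schema: Mapping | str | Path) -> FeatureTable:
    """Load a CSV feature table under a column-kind schema.

    ``schema`` is either a mapping or a path to a JSON sidecar with keys
    ``id_column`` (default ``"patient_id"``), ``target`` (target column name,
    optional), and ``columns`` (predictor name -> kind).
    """
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = json.load(fh)
    id_col = schema.get("id_column", "patient_id")
    target_col = schema.get("target")
    columns: Mapping[str, str] = schema["columns"]

    raw = pd.read_csv(path)
    for col in [id_col, *([target_col] if target_col else []), *columns]:
        if col not in raw.columns:
            raise SchemaError(f"declared column {col!r} not present in {path}")
    frame = raw.set_index(id_col)[list(columns)]
    target = raw.set_index(id_col)[target_col] if target_col else None
    return FeatureTable(frame=frame, kinds=dict(columns), target=target)


def write_feature_table(table: FeatureTable, csv_path: str | Path,
                        schema_path: str | Path | None = None,
                        id_column: str = "patient_id",
                        target_column: str = "target") -> None:
    """Write the table as CSV plus (optionally) its JSON schema sidecar."""
    out = table.frame.copy()
    if table.target is not None:
        out[target_column] = table.target
    out.index.name = id_column
    out.to_csv(csv_path)
    if schema_path is not None:
        schema = {
            "id_column": id_column,
            "target": target_column if table.target is not None else None,
            "columns": {c: table.kinds[c] for c in table.frame.columns},
        }
        with open(schema_path, "w") as fh:
            json.dump(schema, fh, indent=1)  # column order is meaningful


# ---------------------------------------------------------------------------
# Target derivation
# ---------------------------------------------------------------------------

def derive_target(ais_admission: str, ais_discharge: str) -> int:
    """1 iff the discharge grade is strictly better (A<B<C<D<E) than admission."""
    try:
        adm = AIS_GRADES.index(ais_admission)
        dis = AIS_GRADES.index(ais_discharge)
    except ValueError as exc:
        raise ValueError(
            f"unknown AIS grade in ({ais_admission!r}, {ais_discharge!r})"
        ) from exc
    return int(dis > adm)


def derive_targets(admission: pd.Series, discharge: pd.Series) -> pd.Series:
    """Vectorized :func:`derive_target` over aligned grade series."""
    return pd.Series(
        [derive_target(a, d) for a, d in zip(admission, discharge)],
        index=admission.index, dtype=int,
    )


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionPlan:
    """One grouped, target-stratified k-fold assignment.

    ``assignment`` maps record-group ids to fold indices in ``[0, k)``;
    ``groups`` maps each patient to its group, so all members of a group land
    in the same fold by construction.
    """

    seed: int
    k: int
    assignment: Mapping[object, int]
    groups: Mapping[object, object]

    def fold_of(self, patient) -> int:
        return self.assignment[self.groups[patient]]

    def folds(self, patients: Sequence) -> np.ndarray:
        """Fold index per patient, in the given order."""
        return np.asarray([self.fold_of(p) for p in patients], dtype=int)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": int(self.seed), "k": int(self.k),
             "assignment": {str(g): int(f) for g, f in sorted(
                 self.assignment.items(), key=lambda kv: str(kv[0]))}},
            sort_keys=True)


def make_partition_plan(table: FeatureTable, k: int, seed: int,
                        groups: Mapping[object, object] | None = None) -> PartitionPlan:
    """Build a deterministic, grouped, target-stratified k-fold plan.

    Groups (defaulting to one per patient) are dealt round-robin to folds
    within each target class after seeded shuffling, so per-fold class counts
    differ by at most one group per class and no group ever splits.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = table.target
    if y is None:
        raise SchemaError("partitioning requires a labeled table")
    if groups is None:
        groups = {p: p for p in table.patients}
    else:
        groups = dict(groups)
        missing = [p for p in table.patients if p not in groups]
        if missing:
            raise ValueError(f"patients without a group: {missing[:5]}")

    # class of a group = majority target among members (ties -> positive)
    members: dict[object, list] = {}
    for p in table.patients:
        members.setdefault(groups[p], []).append(p)
    group_class = {}
    for g, ps in members.items():
        mean = float(np.mean([y.loc[p] for p in ps]))
        group_class[g] = int(mean >= 0.5)

    rng = np.random.default_rng(seed)
    assignment: dict[object, int] = {}
    for cls in (0, 1):
        gids = sorted((g for g, c in group_class.items() if c == cls), key=str)
        if len(gids) < k:
            raise ValueError(
                f"class {cls} present in only {len(gids)} groups; "
                f"cannot place one in each of {k} folds")
        order = rng.permutation(len(gids))
        fold_order = rng.permutation(k)
        for i, j in enumerate(order):
            assignment[gids[j]] = int(fold_order[i % k])

    plan = PartitionPlan(seed=seed, k=k, assignment=assignment, groups=groups)
    # every fold must see at least one record of each class
    folds = plan.folds(table.patients)
    yarr = y.to_numpy()
    for f in range(k):
        for cls in (0, 1):
            if not np.any((folds == f) & (yarr == cls)):
                raise ValueError(f"fold {f} has no class-{cls} record")
    return plan


@dataclass(frozen=True)
class ProjectSet:
    """Plans for the repeated-CV projects; all share k and the record set."""

    plans: tuple[PartitionPlan, ...]

    def __post_init__(self):
        seeds = [p.seed for p in self.plans]
        if len(set(seeds)) != len(seeds):
            raise ValueError("project seeds must be pairwise distinct")
        if len({p.k for p in self.plans}) > 1:
            raise ValueError("all plans must share k")

    @property
    def k(self) -> int:
        return self.plans[0].k

    def __len__(self) -> int:
        return len(self.plans)

    def __iter__(self):
        return iter(self.plans)


def project_seeds(master_seed: int, n_projects: int) -> list[int]:
    """Derive ``n_projects`` distinct per-project seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s) for s in ss.generate_state(n_projects, dtype=np.uint64)]
    # uint64 collisions are essentially impossible, but stay safe
    while len(set(seeds)) != len(seeds):  # pragma: no cover
        ss = ss.spawn(1)[0]
        seeds = [int(s) for s in ss.generate_state(n_projects, dtype=np.uint64)]
    return seeds


def make_project_set(table: FeatureTable, k: int, n_projects: int,
                     master_seed: int,
                     groups: Mapping[object, object] | None = None) -> ProjectSet:
    """Create ``n_projects`` distinct partition plans from one master seed."""
    if n_projects < 1:
        raise ValueError("n_projects must be >= 1")
    plans = tuple(
        make_partition_plan(table, k=k, seed=s, groups=groups)
        for s in project_seeds(master_seed, n_projects)
    )
    return ProjectSet(plans=plans)


def duplicate_records(table: FeatureTable, suffix: str = "__dup") -> tuple[FeatureTable, dict]:
    """Duplicate every record, returning the doubled table plus a group map
    that keeps each patient and its copy in the same fold.

    Off by default everywhere; provided for parity with platform minimum-size
    workarounds.
    """
    dup = table.frame.copy()
    dup.index = [f"{p}{suffix}" for p in table.frame.index]
    frame = pd.concat([table.frame, dup])
    target = None
    if table.target is not None:
        t2 = table.target.copy()
        t2.index = dup.index
        target = pd.concat([table.target, t2])
    groups = {p: p for p in table.frame.index}
    groups.update({f"{p}{suffix}": p for p in table.frame.index})
    doubled = FeatureTable(frame=frame, kinds=dict(table.kinds), target=target)
    return doubled, groups
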