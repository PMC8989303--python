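# stablecv

Reproducibility-hardened machine-learning workflows for small clinical
cohorts. `stablecv` wraps a repeated k-fold cross-validation strategy
("projects", each with its own partitioning arrangement) around pluggable
preprocessing + estimator *blueprints*, and layers on top of it:

- **Performance precision** — cross-project mean ± 95% CI of LogLoss/AUC and
  the *standardized performance CI width* (CI width / mean × 100), plus a
  without-replacement sampling analysis of how precision scales with the
  number of projects aggregated.
- **Feature instability** — normalized permutation feature importance (pFI)
  aggregated across projects, the *feature rank instability* metric
  (FRI: L1 distance between importance-rank vectors), a bottom-k variant,
  and the matching sampling analysis.
- **Expert-protected backward feature reduction** — iterative elimination of
  the lowest mean-pFI features (step 5, then step 1 inside the best-size
  window), with user-protected features that are never eliminated, and
  parsimonious-model selection by aggregated LogLoss.
- **Stabilized explanations** — per-project partial dependence grids pooled
  into mean ± CI curves.
- **Hemodynamic threshold features** — intraoperative vitals summaries
  (mean/sd/skew/kurtosis for HR, SysBP, DiaBP, MAP), time spent strictly
  above/below MAP thresholds, and a single-threshold sweep (lower 70–85,
  upper 95–115 mmHg; 38 conditions) over fixed partition plans.
- **External-validation drift audit** — per-patient prediction aggregation
  against the mean best-F1 threshold, per-feature population stability index
  (PSI) with drift classes, and pooled-cohort UMAP + HDBSCAN clustering with
  per-cluster summaries.
- **Synthetic cohorts** — a seeded generator of SCI-like cohorts (AR(1)
  vitals traces with excursion episodes, ordinal/binary covariates, a
  calibrated logistic outcome model) plus a drifted validation-cohort
  generator, so the entire pipeline is testable without clinical data.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite (metric oracles, FRI
algebra, precision/instability scaling laws, recovery simulations, and a
bit-identical double run of the full CLI pipeline).

## CLI

All stages communicate through plain-text files in a working directory:

```bash
stablecv simulate --seed 7 --out work/data --with-validation
stablecv run      --data work/data --out work/run --projects 25 --k 10 --seed 7
stablecv stability --results work/run/results_bp_log.json --out work/stab --seed 7
stablecv explain  --data work/data --out work/explain --blueprint bp_log --seed 7
stablecv reduce   --data work/data --out work/red --blueprint bp_log --seed 7 \
                  --protect time_MAP_Avg_below_76
stablecv sweep    --data work/data --out work/sweep \
                  --parsimonious work/red/parsimonious_bp_log.json --seed 7
stablecv validate --data work/data --out work/val \
                  --parsimonious work/red/parsimonious_bp_log.json --seed 7
stablecv drift    --data work/data --out work/drift \
                  --features Time_to_OR,MAP_mean,time_MAP_Avg_below_76 --seed 7
```

Blueprints: `bp_log` (quintile-binned L2 logistic regression), `bp_gbt`
(gradient-boosted trees), `bp_majority` (prevalence benchmark). Every command
is deterministic given its seed; re-running a stage reproduces its outputs
byte for byte.

## Library example

```python
from stablecv import (CohortConfig, simulate_cohort, make_project_set,
                      logistic_blueprint, fit_projects, aggregate,
                      aggregate_pfi)

table, vitals, truth = simulate_cohort(CohortConfig(seed=7))
projects = make_project_set(table, k=10, n_projects=25, master_seed=7)
results = fit_projects(logistic_blueprint(seed=7), table, projects)
print(aggregate([r.cv_logloss for r in results]))
print(aggregate_pfi([r.pfi for r in results]).to_frame().head())
```
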