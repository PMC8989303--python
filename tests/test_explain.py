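import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from stablecv.blueprints import (BlueprintSpec, fit_model, fit_projects,
                                 logistic_blueprint)
from stablecv.core_data import make_partition_plan, make_project_set
from stablecv.explain import (PDPGrid, aggregate_pdp, aggregate_pfi,
                              partial_dependence, pdp_grid_values,
                              permutation_importance,
                              project_partial_dependence,
                              raw_permutation_importance)
from stablecv.metrics_stability import PFIList, logloss, rank_importances

LINEAR = BlueprintSpec(name="lin", estimator="l2-logistic")


def _strong_table(n=300, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = np.column_stack([
        y * 2.5 + rng.normal(0, 0.8, n),   # strong signal
        rng.normal(0, 1, n),               # null, independent of everything
    ])
    return make_table(X, y)


class TestPermutationImportance:
    def test_null_feature_near_zero(self):
        table = _strong_table()
        model = fit_model(LINEAR, table.frame, table.y, table.kinds)
        pfi = permutation_importance(model, table, n_permutations=20, seed=1)
        assert pfi.importance_of("x1") == 1.0
        assert pfi.importance_of("x2") < 0.05

    def test_single_feature_normalizes_to_one(self):
        table = _strong_table()
        sub = table.select(["x1"])
        model = fit_model(LINEAR, sub.frame, sub.y, sub.kinds)
        pfi = permutation_importance(model, sub, n_permutations=5, seed=0)
        assert pfi.importances == (1.0,)

    def test_sampled_matches_exhaustive_oracle(self):
        # n = 6: enumerate all 720 permutations of the raw column
        rng = np.random.default_rng(2)
        y = np.array([0, 1, 0, 1, 0, 1])
        X = np.column_stack([y + rng.normal(0, 0.4, 6), rng.normal(0, 1, 6)])
        table = make_table(X, y)
        model = fit_model(LINEAR, table.frame, table.y, table.kinds)

        base = logloss(y, model.predict_proba(table.frame))
        exhaustive = []
        for col in ("x1", "x2"):
            losses = []
            for perm in itertools.permutations(range(6)):
                frame = table.frame.copy()
                frame[col] = table.frame[col].to_numpy()[list(perm)]
                losses.append(logloss(y, model.predict_proba(frame)))
            exhaustive.append(np.mean(losses) - base)

        sampled = raw_permutation_importance(
            model, table.frame, y, n_permutations=500,
            rng=np.random.default_rng(3))
        np.testing.assert_allclose(sampled, exhaustive, atol=0.05)

    def test_block_permutation_equals_raw_permutation(self, mixed_table):
        # the fast path must agree with shuffling the raw column
        model = fit_model(logistic_blueprint(), mixed_table.frame,
                          mixed_table.y, mixed_table.kinds)
        sigma = np.random.default_rng(4).permutation(mixed_table.n_patients)
        frame = mixed_table.frame.copy()
        frame["severity"] = mixed_table.frame["severity"].to_numpy()[sigma]
        slow = model.predict_proba(frame)
        X = model.preprocessor.transform(mixed_table.frame)
        block = model.blocks["severity"]
        X[:, block] = X[sigma][:, block]
        fast = model.predict_proba_matrix(X)
        np.testing.assert_allclose(slow, fast)

    def test_missing_feature_rejected(self):
        table = _strong_table()
        model = fit_model(LINEAR, table.frame, table.y, table.kinds)
        with pytest.raises(ValueError, match="absent"):
            permutation_importance(model, table.select(["x2"]))

    def test_collinear_duplicate_drops_importance(self):
        rng = np.random.default_rng(6)
        n = 400
        y = rng.integers(0, 2, n)
        x = y * 2.0 + rng.normal(0, 0.8, n)
        lone = make_table(np.column_stack([x, rng.normal(0, 1, n)]), y)
        dup = make_table(np.column_stack([x, rng.normal(0, 1, n), x]), y)

        m1 = fit_model(LINEAR, lone.frame, lone.y, lone.kinds)
        m2 = fit_model(LINEAR, dup.frame, dup.y, dup.kinds)
        raw1 = raw_permutation_importance(m1, lone.frame, y, 10,
                                          np.random.default_rng(0))
        raw2 = raw_permutation_importance(m2, dup.frame, y, 10,
                                          np.random.default_rng(0))
        assert raw2[0] < raw1[0]  # each copy matters less than the lone feature
        assert raw2[2] < raw1[0]

    def test_deterministic(self):
        table = _strong_table(n=80, seed=5)
        model = fit_model(LINEAR, table.frame, table.y, table.kinds)
        a = permutation_importance(model, table, n_permutations=5, seed=9)
        b = permutation_importance(model, table, n_permutations=5, seed=9)
        assert a.importances == b.importances


class TestAggregatePfi:
    def test_identical_lists(self):
        pl = PFIList(("a", "b"), (1.0, 0.4))
        agg = aggregate_pfi([pl, pl, pl])
        assert agg.importances == pytest.approx((1.0, 0.4))
        assert agg.ci_low == pytest.approx(agg.importances, abs=1e-9)

    def test_mean_of_two(self):
        a = PFIList(("A", "B"), (1.0, 0.2))
        b = PFIList(("A", "B"), (0.5, 0.2))
        agg = aggregate_pfi([a, b])
        assert agg.importance_of("A") == pytest.approx(0.75)

    def test_rank_order_follows_means(self):
        rng = np.random.default_rng(7)
        feats = tuple(f"f{i}" for i in range(6))
        lists = [PFIList(feats, tuple(rng.random(6))) for _ in range(5)]
        agg = aggregate_pfi(lists)
        means = np.mean([l.importances for l in lists], axis=0)
        expected = rank_importances(feats, means)
        assert list(agg.ranks.values()) == [int(r) for r in expected]

    def test_too_few_lists(self):
        with pytest.raises(ValueError):
            aggregate_pfi([PFIList(("a",), (1.0,))])

    def test_mismatched_features(self):
        with pytest.raises(ValueError, match="share"):
            aggregate_pfi([PFIList(("a",), (1.0,)), PFIList(("b",), (1.0,))])


class TestPartialDependence:
    def test_ignored_feature_flat(self):
        table = _strong_table(n=100, seed=8)
        sub = table.select(["x1"])
        model = fit_model(LINEAR, sub.frame, sub.y, sub.kinds)
        pdp = partial_dependence(model, table, "x2",
                                 grid=np.linspace(-2, 2, 10))
        assert max(pdp.values) - min(pdp.values) < 1e-9

    def test_monotone_effect(self):
        table = _strong_table(n=400, seed=9)
        model = fit_model(LINEAR, table.frame, table.y, table.kinds)
        pdp = partial_dependence(model, table, "x1",
                                 grid=np.linspace(-2, 4, 15))
        assert (np.diff(pdp.values) >= -1e-12).all()

    def test_quintile_blueprint_piecewise_constant(self):
        table = _strong_table(n=200, seed=10)
        model = fit_model(logistic_blueprint(), table.frame, table.y, table.kinds)
        grid = np.linspace(table.frame["x1"].min(), table.frame["x1"].max(), 40)
        pdp = partial_dependence(model, table, "x1", grid=grid)
        bins = model.preprocessor.state_["x1"]["encoder"].bin_index(np.asarray(grid))
        for b in np.unique(bins):
            vals = np.asarray(pdp.values)[bins == b]
            assert vals.max() - vals.min() < 1e-12

    def test_categorical_grid_levels(self, mixed_table):
        assert pdp_grid_values(mixed_table, "severity") == ("A", "B", "C")

    def test_empty_grid_rejected(self):
        table = _strong_table(n=50)
        model = fit_model(LINEAR, table.frame, table.y, table.kinds)
        with pytest.raises(ValueError, match="empty"):
            partial_dependence(model, table, "x1", grid=[])


class TestAggregatePdp:
    def test_identical_grids(self):
        g = PDPGrid("f", (1.0, 2.0), (0.4, 0.6))
        agg = aggregate_pdp([g, g])
        assert agg.values == pytest.approx((0.4, 0.6))

    def test_two_flat_grids(self):
        a = PDPGrid("f", (0.0, 1.0), (0.4, 0.4))
        b = PDPGrid("f", (0.0, 1.0), (0.6, 0.6))
        agg = aggregate_pdp([a, b])
        assert agg.values == pytest.approx((0.5, 0.5))

    def test_grid_mismatch_rejected(self):
        a = PDPGrid("f", (0.0, 1.0), (0.4, 0.4))
        b = PDPGrid("f", (0.0, 2.0), (0.6, 0.6))
        with pytest.raises(ValueError, match="identical"):
            aggregate_pdp([a, b])

    def test_project_pdp_varies_with_partitioning(self):
        table = _strong_table(n=100, seed=12)
        projects = make_project_set(table, k=4, n_projects=4, master_seed=2)
        results = fit_projects(LINEAR, table, projects, compute_pfi=False,
                               refit_full=False, keep_fold_models=True)
        grid = tuple(np.linspace(-2, 3, 6))
        grids = [project_partial_dependence(r, table, "x1", grid)
                 for r in results]
        agg = aggregate_pdp(grids)
        # different partitioning arrangements -> non-degenerate CI
        widths = np.asarray(agg.ci_high) - np.asarray(agg.ci_low)
        assert widths.max() > 0

    def test_project_pdp_requires_fold_models(self):
        table = _strong_table(n=60, seed=13)
        projects = make_project_set(table, k=3, n_projects=2, master_seed=3)
        results = fit_projects(LINEAR, table, projects, compute_pfi=False,
                               refit_full=False)
        with pytest.raises(ValueError, match="keep_fold_models"):
            project_partial_dependence(results[0], table, "x1")

    def test_cross_project_aggregation(self):
        table = _strong_table(n=120, seed=11)
        projects = make_project_set(table, k=4, n_projects=3, master_seed=1)
        results = fit_projects(LINEAR, table, projects, compute_pfi=False,
                               refit_full=True)
        grid = tuple(np.linspace(-2, 3, 8))
        grids = [partial_dependence(r.model, table, "x1", grid) for r in results]
        agg = aggregate_pdp(grids)
        assert len(agg.values) == 8
        assert all(lo <= m <= hi for lo, m, hi
                   in zip(agg.ci_low, agg.values, agg.ci_high))
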