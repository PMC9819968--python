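"""Random-forest OOB machinery and permutation importance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from ecofoot3d import (
    AnalysisConfig,
    ValidationError,
    category_importance,
    fit_forest,
    importance_ratio,
    oob_mse,
    oob_r2,
    permuted_oob_mse,
    run_importance_analysis,
    variable_importance,
)
from ecofoot3d.data_io import INDICATOR_NAMES
from ecofoot3d.importance import ForestModel


def linear_data(n=120, p=9, seed=0, noise=0.0, coef=None):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, p))
    coef = coef if coef is not None else np.eye(1, p)[0]
    y = X @ coef + rng.normal(0, noise, n)
    return pd.DataFrame(X, columns=[f"X{i+1}" for i in range(p)]), y


class TestFitForest:
    def test_same_seed_is_bit_identical(self):
        X, y = linear_data(seed=3)
        cfg = AnalysisConfig(n_trees=25, seed=11)
        f1, f2 = fit_forest(X, y, cfg), fit_forest(X, y, cfg)
        for t1, t2, o1, o2 in zip(f1.trees, f2.trees, f1.oob, f2.oob):
            np.testing.assert_array_equal(o1, o2)
            np.testing.assert_array_equal(t1.predict(X.values), t2.predict(X.values))

    def test_constant_response_predicts_constant(self):
        X, _ = linear_data(seed=1)
        y = np.full(len(X), 3.25)
        forest = fit_forest(X, y, AnalysisConfig(n_trees=10, seed=0))
        for tree in forest.trees:
            np.testing.assert_allclose(tree.predict(X.values), 3.25)

    def test_bootstrap_and_oob_partition(self):
        X, y = linear_data(n=40, seed=2)
        forest = fit_forest(X, y, AnalysisConfig(n_trees=20, seed=5))
        for boot, oob in zip(forest.inbag, forest.oob):
            assert len(boot) == 40  # size-n bootstrap
            assert set(boot).isdisjoint(oob)
            assert set(boot) | set(oob) == set(range(40))

    def test_every_variable_used_somewhere(self):
        X, y = linear_data(n=32, seed=4, coef=np.ones(9))
        forest = fit_forest(X, y, AnalysisConfig(n_trees=500, seed=9))
        used = set()
        for tree in forest.trees:
            used |= {f for f in tree.tree_.feature if f >= 0}
        assert used == set(range(9))

    def test_too_few_observations_rejected(self):
        X, y = linear_data(n=4)
        with pytest.raises(ValidationError):
            fit_forest(X, y, AnalysisConfig(n_trees=5))


class TestOOBMse:
    def hand_forest(self):
        """One tree that predicts 2 everywhere; OOB rows are both observations."""
        tree = DecisionTreeRegressor().fit([[0.0]], [2.0])
        return ForestModel(
            trees=[tree],
            inbag=[np.array([], dtype=int)],
            oob=[np.array([0, 1])],
            feature_names=("X1",),
            seed=0,
        )

    def test_hand_built_mse(self):
        forest = self.hand_forest()
        X = np.array([[0.0], [1.0]])
        y = np.array([1.0, 3.0])
        np.testing.assert_allclose(oob_mse(forest, X, y), [1.0])

    def test_exact_tree_has_zero_mse(self):
        X, y = linear_data(n=60, seed=6)
        forest = fit_forest(X, y, AnalysisConfig(n_trees=10, seed=0, min_leaf=1))
        # replace OOB sets with in-bag rows: single-tree training error with
        # leaf size 1 on its own sample is 0
        for t, boot in enumerate(forest.inbag):
            forest.oob[t] = np.unique(boot)
        assert np.nanmax(oob_mse(forest, X, y)) == pytest.approx(0.0, abs=1e-12)

    def test_mse_nonnegative(self):
        X, y = linear_data(n=50, seed=8, noise=0.3)
        forest = fit_forest(X, y, AnalysisConfig(n_trees=30, seed=2))
        mse = oob_mse(forest, X, y)
        assert np.nanmin(mse) >= 0


class TestPermutedMse:
    def test_permuting_unused_variable_changes_nothing(self):
        # X2..X9 constant: no tree can split on them
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            {"X1": rng.uniform(0, 1, 80), **{f"X{i}": 1.0 for i in range(2, 10)}}
        )
        y = X["X1"].to_numpy()
        forest = fit_forest(X, y, AnalysisConfig(n_trees=20, seed=1))
        base = oob_mse(forest, X, y)
        permuted = permuted_oob_mse(forest, X, y, "X5", seed=99)
        np.testing.assert_array_equal(base, permuted)

    def test_permuting_the_signal_variable_hurts(self):
        X, y = linear_data(n=150, seed=5)
        forest = fit_forest(X, y, AnalysisConfig(n_trees=50, seed=7))
        base = oob_mse(forest, X, y)
        permuted = permuted_oob_mse(forest, X, y, "X1", seed=0)
        assert np.nanmean(permuted - base) > 0
        assert (permuted[~np.isnan(base)] >= base[~np.isnan(base)]).mean() > 0.9

    def test_fixed_seed_reproducible(self):
        X, y = linear_data(n=60, seed=9, noise=0.2)
        forest = fit_forest(X, y, AnalysisConfig(n_trees=15, seed=3))
        a = permuted_oob_mse(forest, X, y, "X1", seed=42)
        b = permuted_oob_mse(forest, X, y, "X1", seed=42)
        np.testing.assert_array_equal(a, b)

    def test_unknown_variable_rejected(self):
        X, y = linear_data(n=30)
        forest = fit_forest(X, y, AnalysisConfig(n_trees=5, seed=0))
        with pytest.raises(ValidationError):
            permuted_oob_mse(forest, X, y, "X42")


class TestImportance:
    def test_signal_variable_dominates(self):
        X, y = linear_data(n=150, seed=13)
        forest = fit_forest(X, y, AnalysisConfig(n_trees=200, seed=13))
        vi = variable_importance(forest, X, y, seed=13)
        assert max(vi, key=vi.get) == "X1"

    def test_noise_importance_is_small(self):
        X, y = linear_data(n=150, seed=21)
        forest = fit_forest(X, y, AnalysisConfig(n_trees=200, seed=21))
        vi = variable_importance(forest, X, y, seed=21)
        noise_max = max(abs(vi[f"X{i}"]) for i in range(2, 10))
        assert noise_max < 0.05 * vi["X1"]

    def test_constant_response_has_all_zero_vi(self):
        X, _ = linear_data(n=40, seed=2)
        y = np.zeros(len(X))
        forest = fit_forest(X, y, AnalysisConfig(n_trees=20, seed=1))
        vi = variable_importance(forest, X, y, seed=1)
        assert all(v == 0.0 for v in vi.values())
        with pytest.raises(ValidationError):
            importance_ratio(vi)

    @pytest.mark.parametrize(
        "vi,expected",
        [({"a": 3.0, "b": 1.0}, {"a": 0.75, "b": 0.25}), ({"a": 2.0}, {"a": 1.0})],
    )
    def test_ratio_hand_values(self, vi, expected):
        assert importance_ratio(vi) == pytest.approx(expected)

    def test_negative_vi_truncated_by_default(self):
        ratio = importance_ratio({"a": 3.0, "b": -1.0})
        assert ratio == pytest.approx({"a": 1.0, "b": 0.0})
        ratio_abs = importance_ratio({"a": 3.0, "b": -1.0}, negative_vi="absolute")
        assert ratio_abs == pytest.approx({"a": 0.75, "b": 0.25})

    def test_ratios_sum_to_one(self):
        X, y = linear_data(n=100, seed=17, noise=0.2, coef=np.linspace(1, 0.1, 9))
        forest = fit_forest(X, y, AnalysisConfig(n_trees=100, seed=17))
        ratio = importance_ratio(variable_importance(forest, X, y, seed=17))
        assert sum(ratio.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(r >= 0 for r in ratio.values())


class TestOOBR2:
    def test_noiseless_signal_fits_well(self):
        X, y = linear_data(n=200, seed=19)
        forest = fit_forest(X, y, AnalysisConfig(n_trees=500, seed=19))
        assert oob_r2(forest, X, y) > 0.9

    def test_mean_predictor_scores_near_zero(self):
        X, _ = linear_data(n=200, seed=23)
        y = np.random.default_rng(23).normal(size=200)  # pure noise target
        forest = fit_forest(X, y, AnalysisConfig(n_trees=100, seed=23))
        assert oob_r2(forest, X, y) < 0.15

    def test_r2_bounded_above_by_one(self):
        X, y = linear_data(n=80, seed=29, noise=0.5)
        forest = fit_forest(X, y, AnalysisConfig(n_trees=50, seed=29))
        assert oob_r2(forest, X, y) <= 1.0


class TestCategories:
    def test_uniform_ratio_split(self):
        ratio = {name: 1 / 9 for name in INDICATOR_NAMES}
        cats = category_importance(ratio)
        assert cats["economic"] == pytest.approx(2 / 9)
        assert cats["social"] == pytest.approx(3 / 9)
        assert cats["environment"] == pytest.approx(4 / 9)

    def test_uncovered_variable_rejected(self):
        with pytest.raises(ValidationError):
            category_importance({"X1": 0.5, "Z9": 0.5})


class TestPipeline:
    def test_table_layout_and_normalization(self, items, factors):
        from ecofoot3d import (
            ScenarioConfig,
            build_accounts,
            compute_panel_threedef,
            generate_panel,
        )

        records = generate_panel(ScenarioConfig(seed=7))
        accounts = build_accounts(records, items, factors)
        results = compute_panel_threedef(accounts, per_capita=True)
        cfg = AnalysisConfig(n_trees=40, seed=7)
        out = run_importance_analysis(records, results, cfg)
        # 2 responses x (4 years + pooled)
        assert len(out) == 10
        labels = {(r.target_name, r.slice_label) for r in out}
        assert ("ln_ef_depth", "pooled") in labels and ("ln_ef_size", "2000") in labels
        for r in out:
            assert sum(r.ratio.values()) == pytest.approx(1.0, abs=1e-3)
            assert sum(r.category_ratio.values()) == pytest.approx(1.0, abs=1e-9)

    def test_small_slice_warns(self, items, factors, caplog):
        import logging

        from ecofoot3d import ScenarioConfig, build_accounts, compute_panel_threedef, generate_panel

        records = generate_panel(ScenarioConfig(n_cities=8, years=(2000,), seed=3))
        accounts = build_accounts(records, items, factors)
        results = compute_panel_threedef(accounts, per_capita=True)
        with caplog.at_level(logging.WARNING, logger="ecofoot3d.importance"):
            run_importance_analysis(records, results, AnalysisConfig(n_trees=30, seed=3))
        assert any("unstable" in rec.message for rec in caplog.records)
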