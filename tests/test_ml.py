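"""Feature pruning, fold plans, imbalance handling, models, selection, stacking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tadscreen import ml


def frame(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


class TestNZVPrune:
    def test_binary_96_4_removed(self):
        X = frame(np.array([[1] * 96 + [0] * 4]).T)
        assert ml.NearZeroVariancePruner().fit(X).keep_ == []

    def test_binary_50_50_kept(self):
        X = frame(np.array([[1] * 50 + [0] * 50]).T)
        assert ml.NearZeroVariancePruner().fit(X).keep_ == ["f0"]

    def test_constant_removed(self):
        X = frame(np.ones((30, 1)))
        assert ml.NearZeroVariancePruner().fit(X).keep_ == []

    def test_boundary_95_5_kept(self):
        X = frame(np.array([[1] * 95 + [0] * 5]).T)
        assert ml.NearZeroVariancePruner().fit(X).keep_ == ["f0"]


class TestCorrPrune:
    def test_duplicated_column_single_survivor(self, rng):
        base = rng.normal(size=(100, 1))
        X = frame(np.hstack([base, base]))
        pruner = ml.CorrelationPruner().fit(X)
        assert len(pruner.keep_) == 1

    def test_orthogonal_features_all_kept(self, rng):
        X = frame(rng.normal(size=(200, 5)))
        assert len(ml.CorrelationPruner().fit(X).keep_) == 5

    def test_chain_fixture_matches_bruteforce_components(self, rng):
        # f0~f1~f2~f3 form a correlation chain; f4 independent
        base = rng.normal(size=300)
        cols = [base]
        for _ in range(3):
            cols.append(cols[-1] + rng.normal(scale=0.35, size=300))
        cols.append(rng.normal(size=300))
        X = frame(np.column_stack(cols))
        pruner = ml.CorrelationPruner(threshold=0.75).fit(X)
        # brute force: adjacency from |r| >= .75, union-find components,
        # keep per component the min-mean-|r| member
        corr = np.abs(np.corrcoef(X.to_numpy(), rowvar=False))
        parent = list(range(5))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(5), 2):
            if corr[i, j] >= 0.75:
                parent[find(i)] = find(j)
        comps = {}
        for i in range(5):
            comps.setdefault(find(i), []).append(i)
        expected = set()
        for comp in comps.values():
            if len(comp) == 1:
                expected.add(f"f{comp[0]}")
            else:
                scores = [
                    (np.mean([corr[i, j] for j in comp if j != i]), f"f{i}")
                    for i in comp
                ]
                expected.add(min(scores)[1])
        assert set(pruner.keep_) == expected

    def test_forced_keep_retained(self, rng):
        base = rng.normal(size=(100, 1))
        X = frame(np.hstack([base, base * 1.0000001]))
        pruner = ml.CorrelationPruner(forced_keep=("f1",)).fit(X)
        assert "f1" in pruner.keep_


class TestLinCombPrune:
    def test_exact_sum_dependency_removed(self, rng):
        a = rng.normal(size=(80, 2))
        X = frame(np.column_stack([a[:, 0], a[:, 1], a[:, 0] + a[:, 1]]))
        pruner = ml.LinearCombinationPruner().fit(X)
        reduced = pruner.transform(X)
        assert reduced.shape[1] == 2
        assert np.linalg.matrix_rank(reduced.to_numpy()) == 2
        # rank preserved by the removal
        assert np.linalg.matrix_rank(X.to_numpy()) == 2

    def test_full_rank_matrix_unchanged(self, rng):
        X = frame(rng.normal(size=(50, 6)))
        assert ml.LinearCombinationPruner().fit(X).keep_ == list(X.columns)


class TestCenterScale:
    def test_training_columns_standardized_validation_frozen(self, rng):
        X = frame(rng.normal(loc=5, scale=3, size=(100, 4)))
        pre = ml.make_preprocessor(forced_keep=()).fit(X)
        Xt = np.asarray(pre.transform(X))
        np.testing.assert_allclose(Xt.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Xt.std(axis=0), 1, atol=1e-12)
        # validation rows use training parameters, not a refit
        Xv = frame(rng.normal(loc=50, scale=3, size=(20, 4)))
        Xvt = np.asarray(pre.transform(Xv))
        assert Xvt.mean() > 5

    def test_zero_variance_column_no_blowup(self):
        from sklearn.preprocessing import StandardScaler

        X = np.column_stack([np.ones(30), np.arange(30.0)])
        Xt = StandardScaler().fit_transform(X)
        assert np.all(np.isfinite(Xt))


class TestSplitsAndFolds:
    def _dataset(self, n=400, prev=0.1, seed=0):
        r = np.random.default_rng(seed)
        X = frame(r.normal(size=(n, 3)))
        y = (r.random(n) < prev).astype(int)
        y[:2] = 1  # both classes guaranteed
        return ml.MLDataset(X=X, y=y)

    def test_holdout_sizes_and_stratification(self):
        ds = self._dataset()
        train, test = ml.split_holdout(ds, seed=1)
        assert len(train.y) == 300 and len(test.y) == 100
        assert abs(train.y.mean() - test.y.mean()) < 0.05

    def test_holdout_deterministic(self):
        ds = self._dataset()
        t1, _ = ml.split_holdout(ds, seed=3)
        t2, _ = ml.split_holdout(ds, seed=3)
        assert t1.X.equals(t2.X)

    def test_repeated_kfold_plan_coverage(self):
        y = np.array([0] * 90 + [1] * 10)
        folds = ml.make_folds(y, "repeated_kfold", k=5, repeats=10, seed=0)
        assert len(folds) == 50
        for tr, va in folds:
            assert len(np.intersect1d(tr, va)) == 0
        # every row validates exactly once per repeat
        counts = np.zeros(100)
        for _, va in folds[:5]:
            counts[va] += 1
        assert (counts == 1).all()

    def test_group_kfold_never_splits_a_group(self):
        r = np.random.default_rng(1)
        groups = np.repeat([f"tad{i}" for i in range(13)], 20)
        y = (r.random(len(groups)) < 0.3).astype(int)
        folds = ml.make_folds(y, "group_kfold", groups=groups, k=5, repeats=10, seed=2)
        assert len(folds) == 50
        sizes = []
        for tr, va in folds:
            tr_groups = set(groups[tr])
            va_groups = set(groups[va])
            assert not (tr_groups & va_groups)
            sizes.append(len(va_groups))
        # 13 groups over 5 folds: validation folds hold 3,3,3,2,2 groups
        assert sorted(sizes[:5], reverse=True) == [3, 3, 3, 2, 2]

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            ml.make_folds(np.zeros(10), "group_kfold",
                          groups=np.repeat(["a", "b"], 5), k=5)


class TestSubsample:
    def test_downsamples_majority_to_minority(self):
        y = np.array([1] * 739 + [0] * 63385)
        idx = ml.subsample_minority(y, seed=0)
        assert (y[idx] == 1).sum() == 739
        assert (y[idx] == 0).sum() == 739

    def test_seeded_determinism(self):
        y = np.array([1] * 20 + [0] * 200)
        i1 = ml.subsample_minority(y, seed=5)
        i2 = ml.subsample_minority(y, seed=5)
        np.testing.assert_array_equal(i1, i2)

    def test_per_origin_stratification(self):
        y = np.array([1] * 10 + [0] * 90 + [1] * 40 + [0] * 60)
        origin = np.array(["random"] * 100 + ["design"] * 100)
        idx = ml.subsample_minority(y, seed=1, origin=origin)
        for o in ("random", "design"):
            sel = idx[origin[idx] == o]
            assert (y[sel] == 1).sum() == (y[sel] == 0).sum()

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            ml.subsample_minority(np.zeros(10, dtype=int))


class TestGridsAndModels:
    def test_lambda_grid_has_50_values_spanning_range(self):
        grid = ml.lambda_grid()
        assert len(grid) == 50
        assert grid[0] == pytest.approx(1e-5)
        assert grid[-1] == pytest.approx(0.1)
        steps = np.diff(grid)
        np.testing.assert_allclose(steps, steps[0])  # evenly interspersed

    def test_boosted_grid_enumerates_32_combinations(self):
        grid = ml.boosted_grid()
        assert len(grid) == 32
        assert len({tuple(sorted(g.items())) for g in grid}) == 32
        assert all(g["colsample_bytree"] == 0.8 and g["gamma"] == 0 for g in grid)

    def test_l1_at_huge_lambda_zeroes_all_coefficients(self, rng):
        X = rng.normal(size=(100, 8))
        y = (X[:, 0] > 0).astype(int)
        model = ml.train_model(X, y, "penalized_L1", {"lambda": 100.0})
        np.testing.assert_allclose(model.coef_, 0)

    def test_nonfinite_features_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            ml.train_model(X, np.array([0, 1]), "penalized_L2", {"lambda": 0.01})


class TestEvaluate:
    def test_perfect_separation(self):
        y = np.array([0] * 50 + [1] * 50)
        p = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)])
        res = ml.evaluate(p, y)
        assert res["pr_auc"] == 1.0 and res["roc_auc"] == 1.0

    def test_random_scores_near_prevalence_baseline(self):
        r = np.random.default_rng(7)
        n = 100_000
        y = (r.random(n) < 0.01).astype(int)
        p = r.random(n)
        res = ml.evaluate(p, y)
        assert res["pr_auc"] == pytest.approx(0.01, abs=0.005)
        assert res["roc_auc"] == pytest.approx(0.5, abs=0.02)
        assert res["baseline_pr_auc"] == pytest.approx(y.mean())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ml.evaluate([0.2, 0.8], [1, 1])


class TestOneSERule:
    def test_single_candidate(self):
        res = [ml.GridPointResult("penalized_L1", {"lambda": 0.1}, [0.5, 0.6])]
        assert ml.select_one_se(res) is res[0]

    def test_simpler_model_within_one_se_chosen(self):
        complex_model = ml.GridPointResult(
            "boosted",
            {"n_estimators": 100, "max_depth": 4, "learning_rate": 0.3,
             "min_child_weight": 1, "subsample": 0.75},
            [0.76, 0.84, 0.80, 0.80],  # mean .80, se ~.016
        )
        simple_model = ml.GridPointResult(
            "boosted",
            {"n_estimators": 30, "max_depth": 2, "learning_rate": 0.3,
             "min_child_weight": 1, "subsample": 0.75},
            [0.79, 0.79, 0.79, 0.79],  # mean .79 within one SE
        )
        chosen = ml.select_one_se([complex_model, simple_model])
        assert chosen is simple_model

    def test_boosted_ordering_rounds_before_depth(self):
        few_deep = ml.GridPointResult(
            "boosted",
            {"n_estimators": 30, "max_depth": 4, "learning_rate": 0.1,
             "min_child_weight": 1, "subsample": 0.5},
            [0.8, 0.8],
        )
        many_shallow = ml.GridPointResult(
            "boosted",
            {"n_estimators": 100, "max_depth": 2, "learning_rate": 0.1,
             "min_child_weight": 1, "subsample": 0.5},
            [0.8, 0.8],
        )
        assert ml.select_one_se([few_deep, many_shallow]) is few_deep

    def test_penalized_larger_lambda_is_simpler(self):
        small = ml.GridPointResult("penalized_L1", {"lambda": 0.001}, [0.8, 0.8])
        large = ml.GridPointResult("penalized_L1", {"lambda": 0.09}, [0.8, 0.8])
        assert ml.select_one_se([small, large]) is large


class TestStacking:
    def _oof(self, n=300, seed=0):
        r = np.random.default_rng(seed)
        y = (r.random(n) < 0.3).astype(int)
        signal = y + r.normal(0, 0.6, n)
        probs = 1 / (1 + np.exp(-signal))
        return pd.DataFrame({"m1": probs}), y

    def test_single_base_model_rank_passthrough(self):
        P, y = self._oof()
        stack = ml.stack_models(P, y, seed=1)
        combined = stack.predict_proba(P.to_numpy())[:, 1]
        # monotone transform of the single base probability
        order = np.argsort(P["m1"].to_numpy())
        assert (np.diff(combined[order]) >= -1e-12).all()

    def test_bootstrap_count_recorded(self):
        P, y = self._oof()
        assert ml.stack_models(P, y, n_bootstrap=50, seed=0).n_bootstrap == 50

    def test_seeded_determinism(self):
        P, y = self._oof()
        s1 = ml.stack_models(P, y, seed=9)
        s2 = ml.stack_models(P, y, seed=9)
        np.testing.assert_array_equal(s1.weights, s2.weights)
        assert s1.intercept == s2.intercept


class TestImportance:
    def _fitted(self, rng):
        X = rng.normal(size=(300, 5))
        y = (X[:, 0] - X[:, 1] + 0.3 * rng.normal(size=300) > 0).astype(int)
        names = [f"f{i}" for i in range(5)]
        models = {
            "penalized_L1": ml.train_model(X, y, "penalized_L1", {"lambda": 0.005}),
            "boosted": ml.train_model(
                X, y, "boosted",
                {"n_estimators": 30, "max_depth": 2, "learning_rate": 0.3,
                 "min_child_weight": 1, "subsample": 0.75, "colsample_bytree": 0.8,
                 "gamma": 0},
            ),
        }
        return models, names, X, y

    def test_percentages_sum_to_100_per_method(self, rng):
        models, names, X, y = self._fitted(rng)
        table = ml.importance_table(models, names, X, y)
        sums = table.groupby("method")["importance_pct"].sum()
        np.testing.assert_allclose(sums, 100, rtol=1e-9)

    def test_negative_only_feature_directed_down(self, rng):
        models, names, X, y = self._fitted(rng)
        table = ml.importance_table(models, names, X, y)
        l1 = table[table["method"] == "penalized_L1"].set_index("feature")
        assert l1.loc["f0", "direction"] == "up"
        assert l1.loc["f1", "direction"] == "down"


class TestNoLeak:
    def test_preprocessor_parameters_ignore_validation_rows(self, rng):
        """Audit: perturbing rows outside the training fold cannot change
        any fitted preprocessing parameter."""
        X = frame(rng.normal(size=(120, 6)))
        train_rows = np.arange(80)
        pre1 = ml.make_preprocessor(forced_keep=()).fit(X.iloc[train_rows])
        X_perturbed = X.copy()
        X_perturbed.iloc[80:] += 100.0
        pre2 = ml.make_preprocessor(forced_keep=()).fit(X_perturbed.iloc[train_rows])
        assert pre1.named_steps["lincomb"].keep_ == pre2.named_steps["lincomb"].keep_
        # identical up to float summation order (pandas block layout changes)
        np.testing.assert_allclose(
            pre1.named_steps["scale"].mean_, pre2.named_steps["scale"].mean_,
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            pre1.named_steps["scale"].scale_, pre2.named_steps["scale"].scale_,
            rtol=1e-12,
        )


class TestClassifierEndToEnd:
    def test_fit_predict_and_reproducibility(self):
        r = np.random.default_rng(3)
        n = 500
        X = frame(r.normal(size=(n, 12)))
        logits = 1.5 * X["f0"] - 1.0 * X["f1"] + r.normal(0, 0.5, n)
        y = (logits > np.quantile(logits, 0.9)).astype(int).to_numpy()
        small_boost = [{"learning_rate": 0.3, "max_depth": 2, "subsample": 0.75,
                        "n_estimators": 30, "min_child_weight": 1,
                        "colsample_bytree": 0.8, "gamma": 0}]
        kw = dict(repeats=2, n_lambda=5, boosted_params=small_boost,
                  n_bootstrap=20, forced_keep=(), random_state=7)
        clf1 = ml.TADActivityClassifier(**kw).fit(X, y)
        clf2 = ml.TADActivityClassifier(**kw).fit(X, y)
        p1 = clf1.predict_proba(X)[:, 1]
        p2 = clf2.predict_proba(X)[:, 1]
        np.testing.assert_allclose(p1, p2, atol=1e-10)
        res = ml.evaluate(p1, y)
        assert res["pr_auc"] > 3 * res["baseline_pr_auc"]
        # importance identifies the informative features
        top = clf1.top_features("stacked", 2)["feature"].tolist()
        assert "f0" in top and "f1" in top

    def test_sklearn_get_set_params_roundtrip(self):
        clf = ml.TADActivityClassifier(repeats=3)
        params = clf.get_params()
        clf.set_params(**params)
        assert clf.get_params()["repeats"] == 3
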