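"""Fold construction, splitting, selection, cross-testing, and the three
scheme estimators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from crosstest import (
    CrossValidationAndCrossTest,
    CrossValidationAndTest,
    Dataset,
    NestedCrossValidation,
    RandomSpec,
    SplitConfig,
    cross_test,
    default_grid,
    evaluate_cv_and_crosstest,
    evaluate_cv_and_test,
    fit_model,
    generate_random,
    make_folds,
    model_accuracy,
    select_params_cv,
    split_cv_test,
)
from crosstest.grid import ParamCombo, ParamGrid

from conftest import BruteNN, brute_nn_predict

ONE_COMBO = ParamGrid((ParamCombo(use_pca=False, c_penalty=1.0),))


class TestMakeFolds:
    def test_balanced_ten_into_five(self):
        y = np.tile([0, 1], 5)
        folds = make_folds(y, 5, np.random.default_rng(0))
        for f in range(1, 6):
            idx = folds.indices(f)
            assert len(idx) == 2
            assert set(y[idx]) == {0, 1}

    def test_single_fold_holds_everything(self):
        y = np.tile([0, 1], 5)
        folds = make_folds(y, 1, np.random.default_rng(0))
        assert np.array_equal(folds.indices(1), np.arange(10))

    def test_seven_samples_three_folds(self):
        # 4/3 class split dealt round-robin -> total sizes {3,2,2}
        y = np.array([0, 0, 0, 0, 1, 1, 1])
        folds = make_folds(y, 3, np.random.default_rng(1))
        sizes = sorted(len(folds.indices(f)) for f in range(1, 4))
        assert sizes == [2, 2, 3]
        for cls in (0, 1):
            per_fold = [np.sum(y[folds.indices(f)] == cls) for f in range(1, 4)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_more_folds_than_samples_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array([0, 1]), 3, np.random.default_rng(0))

    @given(
        n0=st.integers(1, 15),
        n1=st.integers(1, 15),
        k=st.integers(1, 8),
        seed=st.integers(0, 10),
    )
    def test_partition_invariants(self, n0, n1, k, seed):
        y = np.random.default_rng(seed).permutation(np.repeat([0, 1], [n0, n1]))
        if k > len(y):
            return
        folds = make_folds(y, k, np.random.default_rng(seed))
        all_idx = np.concatenate([folds.indices(f) for f in range(1, k + 1)])
        assert sorted(all_idx) == list(range(len(y)))  # disjoint cover
        for cls in (0, 1):
            per_fold = [int(np.sum(y[folds.indices(f)] == cls)) for f in range(1, k + 1)]
            assert max(per_fold) - min(per_fold) <= 1


class TestSplitCvTest:
    def test_balanced_half_split(self):
        y = np.tile([0, 1], 50)
        cv, test = split_cv_test(y, 0.5, np.random.default_rng(0))
        assert len(cv) == len(test) == 50
        assert np.sum(y[test] == 0) == np.sum(y[test] == 1) == 25

    def test_ninety_percent_test(self):
        y = np.tile([0, 1], 50)
        cv, test = split_cv_test(y, 0.9, np.random.default_rng(0))
        assert len(cv) == 10
        assert np.sum(y[cv] == 0) == np.sum(y[cv] == 1) == 5

    def test_seed_determinism(self):
        y = np.tile([0, 1], 50)
        a = split_cv_test(y, 0.3, np.random.default_rng(5))
        b = split_cv_test(y, 0.3, np.random.default_rng(5))
        c = split_cv_test(y, 0.3, np.random.default_rng(6))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert not np.array_equal(a[1], c[1])

    def test_disjoint_union(self):
        y = np.random.default_rng(2).permutation(np.repeat([0, 1], [13, 17]))
        cv, test = split_cv_test(y, 0.4, np.random.default_rng(0))
        assert sorted(np.concatenate([cv, test])) == list(range(30))

    def test_too_small_class_reported(self):
        y = np.array([0, 0, 0, 0, 0, 0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="class"):
            split_cv_test(y, 0.9, np.random.default_rng(0))


class TestSelectParamsCv:
    def test_single_combo_equals_plain_kfold_cv(self):
        rng = np.random.default_rng(4)
        X = rng.random((20, 3))
        y = rng.permutation(np.repeat([0, 1], 10))
        selection, _ = select_params_cv(
            X, y, ONE_COMBO, 4, np.random.default_rng(9), estimator=BruteNN()
        )
        # independent recomputation: same fold draw, brute-force predictor
        folds = make_folds(y, 4, np.random.default_rng(9))
        accs = []
        for f in range(1, 5):
            mask = folds.fold_of == f
            preds = brute_nn_predict(X[~mask], y[~mask], X[mask])
            accs.append(np.mean(preds == y[mask]))
        assert selection.best == ONE_COMBO.combos[0]
        assert selection.mean_cv_accuracy[selection.best] == pytest.approx(np.mean(accs))

    def test_per_fold_accuracies_match_hand_enumeration(self):
        # 10 fixed points; expected mean CV accuracy enumerated with the
        # free-function 1-NN, independently of the estimator machinery
        X = np.array(
            [[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [1.0, 1.0], [0.9, 1.0],
             [1.0, 0.9], [0.5, 0.5], [0.6, 0.5], [0.2, 0.8], [0.8, 0.2]]
        )
        y = np.array([0, 0, 0, 1, 1, 1, 0, 1, 0, 1])
        selection, _ = select_params_cv(
            X, y, ONE_COMBO, 5, np.random.default_rng(3), estimator=BruteNN()
        )
        folds = make_folds(y, 5, np.random.default_rng(3))
        expected = np.mean(
            [
                np.mean(
                    brute_nn_predict(
                        X[folds.fold_of != f], y[folds.fold_of != f], X[folds.fold_of == f]
                    )
                    == y[folds.fold_of == f]
                )
                for f in range(1, 6)
            ]
        )
        assert selection.mean_cv_accuracy[selection.best] == pytest.approx(expected)

    def test_ties_broken_by_grid_order(self):
        # a plug-in estimator ignores combo parameters, so all combos tie
        grid = ParamGrid(
            (ParamCombo(False, 0.5), ParamCombo(False, 1.0), ParamCombo(False, 2.0))
        )
        rng = np.random.default_rng(6)
        X = rng.random((16, 2))
        y = rng.permutation(np.repeat([0, 1], 8))
        selection, _ = select_params_cv(
            X, y, grid, 4, np.random.default_rng(0), estimator=BruteNN()
        )
        accs = set(selection.mean_cv_accuracy.values())
        assert len(accs) == 1
        assert selection.best == grid.combos[0]

    def test_table_covers_grid(self):
        grid = default_grid()
        rng = np.random.default_rng(8)
        X = rng.random((30, 4))
        y = rng.permutation(np.repeat([0, 1], 15))
        selection, _ = select_params_cv(X, y, grid, 5, np.random.default_rng(1))
        assert set(selection.mean_cv_accuracy) == set(grid.combos)
        best_acc = selection.mean_cv_accuracy[selection.best]
        assert best_acc == max(selection.mean_cv_accuracy.values())


class TestCrossTest:
    def _split_data(self, seed, n=40, d=3):
        rng = np.random.default_rng(seed)
        X = rng.random((n, d))
        y = rng.permutation(np.repeat([0, 1], n // 2))
        cv, test = split_cv_test(y, 0.5, rng)
        return X[cv], y[cv], X[test], y[test]

    def test_k1_reduces_to_holdout_exactly(self):
        combo = ONE_COMBO.combos[0]
        for seed in range(5):
            Xc, yc, Xt, yt = self._split_data(seed)
            acc, _ = cross_test(
                Xc, yc, Xt, yt, combo, 1, np.random.default_rng(0), estimator=BruteNN()
            )
            model = fit_model(Xc, yc, combo, estimator=BruteNN())
            assert acc == model_accuracy(model, Xt, yt)

    def test_separable_clouds_always_perfect(self, separable_clouds):
        y = separable_clouds.labels
        cv, test = split_cv_test(y, 0.5, np.random.default_rng(0))
        for k_test in (1, 2, 5):
            acc, _ = cross_test(
                separable_clouds.features[cv], y[cv],
                separable_clouds.features[test], y[test],
                ParamCombo(False, 1.0), k_test, np.random.default_rng(1),
            )
            assert acc == 1.0

    def test_twelve_points_match_independent_enumeration(self):
        # fixed 12-point layout, k_test=3: recompute each fold's accuracy
        # with the free-function 1-NN on the augmented training set
        rng = np.random.default_rng(12)
        Xc = rng.random((6, 2))
        yc = np.array([0, 0, 0, 1, 1, 1])
        Xt = rng.random((6, 2))
        yt = np.array([0, 1, 0, 1, 0, 1])
        acc, _ = cross_test(
            Xc, yc, Xt, yt, ONE_COMBO.combos[0], 3,
            np.random.default_rng(7), estimator=BruteNN(),
        )
        folds = make_folds(yt, 3, np.random.default_rng(7))
        fold_accs = []
        for f in range(1, 4):
            mask = folds.fold_of == f
            train_X = np.vstack([Xc, Xt[~mask]])
            train_y = np.concatenate([yc, yt[~mask]])
            preds = brute_nn_predict(train_X, train_y, Xt[mask])
            fold_accs.append(np.mean(preds == yt[mask]))
        assert acc == pytest.approx(np.mean(fold_accs))

    def test_k_exceeding_test_size_rejected(self):
        Xc, yc, Xt, yt = self._split_data(0, n=12)
        with pytest.raises(ValueError, match="k_test"):
            cross_test(Xc, yc, Xt, yt, ONE_COMBO.combos[0], 7, np.random.default_rng(0))

    def test_pooled_aggregate_weights_by_fold_size(self):
        Xc, yc, Xt, yt = self._split_data(3, n=30)  # test set of 15 -> uneven folds
        for aggregate in ("mean", "pooled"):
            acc, _ = cross_test(
                Xc, yc, Xt, yt, ONE_COMBO.combos[0], 2,
                np.random.default_rng(2), estimator=BruteNN(), aggregate=aggregate,
            )
            assert 0 <= acc <= 1


class TestSchemeEstimators:
    def _dataset(self, seed, n=60):
        return generate_random(RandomSpec(n_samples=n, n_features=4, seed=seed))

    def test_shared_selection_stage(self):
        # identical seed -> identical split and identical selected combo
        data = self._dataset(0, n=80)
        a = CrossValidationAndTest(random_state=11).fit(data.features, data.labels)
        b = CrossValidationAndCrossTest(random_state=11).fit(data.features, data.labels)
        assert np.array_equal(a.cv_indices_, b.cv_indices_)
        assert a.best_params_ == b.best_params_
        assert a.selection_.mean_cv_accuracy == b.selection_.mean_cv_accuracy

    def test_crosstest_k1_equals_plain_testing(self):
        data = self._dataset(5, n=50)
        plain = CrossValidationAndTest(
            grid=ONE_COMBO, estimator=BruteNN(), random_state=3
        ).fit(data.features, data.labels)
        k1 = CrossValidationAndCrossTest(
            grid=ONE_COMBO, k_test=1, estimator=BruteNN(), random_state=3
        ).fit(data.features, data.labels)
        assert k1.accuracy_ == plain.accuracy_

    def test_fit_determinism(self):
        data = self._dataset(2)
        accs = [
            CrossValidationAndCrossTest(random_state=9)
            .fit(data.features, data.labels)
            .accuracy_
            for _ in range(2)
        ]
        assert accs[0] == accs[1]

    def test_separable_clouds_perfect_for_all_schemes(self, separable_clouds):
        X, y = separable_clouds.features, separable_clouds.labels
        assert CrossValidationAndTest(random_state=0).fit(X, y).accuracy_ == 1.0
        assert CrossValidationAndCrossTest(random_state=0).fit(X, y).accuracy_ == 1.0
        assert NestedCrossValidation(random_state=0).fit(X, y).accuracy_ == 1.0

    def test_nested_has_no_single_selection(self):
        data = self._dataset(3)
        est = NestedCrossValidation(random_state=1).fit(data.features, data.labels)
        assert est.result().selection is None
        assert len(est.fold_params_) == 5

    def test_nested_single_combo_matches_independent_enumeration(self):
        data = self._dataset(7, n=40)
        est = NestedCrossValidation(
            grid=ONE_COMBO, estimator=BruteNN(), random_state=4
        ).fit(data.features, data.labels)
        # reconstruct the outer folds from the audit trail: the final-model
        # records are exactly those whose train+eval sets cover all samples
        n = data.n_samples
        outer = [
            (sorted(tr), sorted(ev))
            for tr, ev in est.audit_
            if len(tr) + len(ev) == n
        ]
        assert len(outer) == 5
        accs = []
        for tr, ev in outer:
            preds = brute_nn_predict(
                data.features[list(tr)], data.labels[list(tr)], data.features[list(ev)]
            )
            accs.append(np.mean(preds == data.labels[list(ev)]))
        assert est.accuracy_ == pytest.approx(np.mean(accs))

    def test_chance_level_on_null_data(self):
        accs = [
            evaluate_cv_and_test(self._dataset(seed, n=80), seed=seed).accuracy
            for seed in range(10)
        ]
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_functional_wrappers_match_estimators(self):
        data = self._dataset(1, n=60)
        res = evaluate_cv_and_crosstest(data, split=SplitConfig(test_fraction=0.4), seed=8)
        est = CrossValidationAndCrossTest(test_fraction=0.4, random_state=8).fit(
            data.features, data.labels
        )
        assert res.accuracy == est.accuracy_
        assert res.selection.best == est.best_params_

    def test_split_config_validation(self):
        with pytest.raises(ValueError):
            SplitConfig(test_fraction=1.0)
        with pytest.raises(ValueError):
            SplitConfig(k_select=1)

    def test_crosstest_training_sets_contain_cv_set(self):
        data = self._dataset(6, n=50)
        est = CrossValidationAndCrossTest(random_state=2).fit(data.features, data.labels)
        cv_set = set(est.cv_indices_.tolist())
        test_set = set(est.test_indices_.tolist())
        testing_records = [
            (tr, ev) for tr, ev in est.audit_ if ev <= frozenset(test_set)
            and tr >= frozenset(cv_set)
        ]
        # all k_test cross-testing fits include the full CV set
        assert len(testing_records) == est.k_test
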