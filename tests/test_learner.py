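"""Fold construction, linear SVM contract, accuracy curve and 1-SD rule."""

import numpy as np
import pytest

from mrmrsvm import (
    AccuracyCurve,
    ExpressionMatrix,
    FeatureSelectingSVM,
    LabeledDataset,
    LinearModel,
    accuracy_curve,
    select_r_star,
    stratified_folds,
    train_linear_svm,
)


def _dataset(X, y, stage="zscore"):
    X = np.asarray(X, dtype=float)
    m = ExpressionMatrix(
        feature_ids=[f"F{i}" for i in range(X.shape[0])],
        sample_ids=[f"s{j}" for j in range(X.shape[1])],
        values=X,
        stage=stage,
    )
    return LabeledDataset(matrix=m, y=np.asarray(y, dtype=bool))


class TestStratifiedFolds:
    def test_small_cohort_pigeonhole(self, rng):
        y = np.array([True] * 12 + [False] * 8)
        ds = _dataset(rng.normal(size=(2, 20)), y)
        folds = stratified_folds(ds, k=10, seed=3)
        sizes = [len(f) for f in folds]
        assert sizes == [2] * 10
        pos_per_fold = [
            sum(ds.y[ds.matrix.sample_ids.index(s)] for s in f) for f in folds
        ]
        assert set(pos_per_fold) <= {1, 2}

    def test_study_sized_cohort_balance(self, rng):
        y = np.array([True] * 112 + [False] * 64)
        ds = _dataset(rng.normal(size=(2, 176)), y)
        folds = stratified_folds(ds, k=10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {17, 18}
        pos = [sum(ds.y[ds.matrix.sample_ids.index(s)] for s in f) for f in folds]
        assert set(pos) <= {11, 12}
        # disjoint cover
        all_ids = sorted(s for f in folds for s in f)
        assert all_ids == sorted(ds.matrix.sample_ids)

    def test_deterministic_given_seed(self, rng):
        y = rng.random(40) < 0.5
        ds = _dataset(rng.normal(size=(2, 40)), y)
        assert stratified_folds(ds, 5, seed=9) == stratified_folds(ds, 5, seed=9)
        assert stratified_folds(ds, 5, seed=9) != stratified_folds(ds, 5, seed=10)

    def test_more_folds_than_samples_rejected(self, rng):
        y = np.array([True] * 3 + [False] * 3)
        ds = _dataset(rng.normal(size=(1, 6)), y)
        with pytest.raises(ValueError, match="folds"):
            stratified_folds(ds, k=7, seed=0)

    def test_class_smaller_than_k_still_balanced(self, rng):
        # a class may hold fewer samples than there are folds; sizes stay even
        y = np.array([True] * 16 + [False] * 4)
        ds = _dataset(rng.normal(size=(1, 20)), y)
        folds = stratified_folds(ds, k=10, seed=1)
        assert sorted(len(f) for f in folds) == [2] * 10


class TestLinearSVM:
    def test_symmetric_pair_boundary_at_zero(self):
        ds = _dataset([[-1.0, 1.0]], [False, True])
        model = train_linear_svm(ds, ["F0"])
        assert model.predict({"F0": [-1.0]})[0] == "negative"
        assert model.predict({"F0": [1.0]})[0] == "positive"
        # boundary: w*x + w0 = 0 at x = 0
        assert model.decision_values({"F0": [0.0]})[0] == pytest.approx(0.0, abs=1e-9)

    def test_max_margin_midpoint(self):
        ds = _dataset([[0.0, 2.0]], [False, True])
        model = train_linear_svm(ds, ["F0"])
        # hard-margin solution: w = 1, w0 = -1, boundary at x = 1
        boundary = -model.threshold / model.weights[0]
        assert boundary == pytest.approx(1.0, abs=1e-6)

    def test_separable_2d_training_accuracy_one(self, rng):
        n = 40
        y = np.arange(n) % 2 == 0
        X = np.vstack(
            [np.where(y, 2.0, -2.0) + rng.normal(0, 0.2, n), rng.normal(size=n)]
        )
        ds = _dataset(X, y)
        model = train_linear_svm(ds, ["F0", "F1"])
        pred = model.predict(ds.matrix.to_frame())
        assert np.all((pred == "positive") == y)

    def test_duplication_invariance_on_separable_data(self, rng):
        y = np.array([False] * 5 + [True] * 5)
        X = np.vstack([np.where(y, 1.5, -1.5) + rng.normal(0, 0.1, 10)])
        ds = _dataset(X, y)
        base = train_linear_svm(ds, ["F0"])
        # duplicate one sample of each class
        X2 = np.hstack([X, X[:, [0, 5]]])
        y2 = np.concatenate([y, [False, True]])
        ds2 = LabeledDataset(
            ExpressionMatrix(
                ["F0"], [f"t{j}" for j in range(12)], X2, stage="zscore"
            ),
            y2,
        )
        dup = train_linear_svm(ds2, ["F0"])
        grid = {"F0": np.linspace(-2, 2, 41)}
        np.testing.assert_array_equal(base.predict(grid), dup.predict(grid))

    def test_empty_subset_rejected(self, zscored_dataset):
        with pytest.raises(ValueError):
            train_linear_svm(zscored_dataset, [])

    def test_predict_sign_convention(self):
        m = LinearModel(features=["F0"], weights=[1.0], threshold=-1.0)
        assert m.predict({"F0": [2.0]})[0] == "positive"
        assert m.predict({"F0": [0.0]})[0] == "negative"
        assert m.predict({"F0": [1.0]})[0] == "positive"  # tie -> positive

    def test_missing_feature_named(self):
        m = LinearModel(features=["F0", "F9"], weights=[1.0, 2.0], threshold=0.0)
        with pytest.raises(KeyError, match="F9"):
            m.predict({"F0": [1.0]})

    def test_model_json_round_trip(self):
        m = LinearModel(["A", "B"], [0.5, -1.5], 0.25, training_stage="zscore")
        back = LinearModel.from_json(m.to_json())
        assert back.features == m.features
        np.testing.assert_allclose(back.weights, m.weights)
        assert back.threshold == m.threshold


class TestSelectRStar:
    def test_one_sd_rule_pattern(self):
        curve = AccuracyCurve(
            r_values=[1, 2, 3, 4],
            mean=[0.80, 0.85, 0.92, 0.93],
            sd=[0.01, 0.01, 0.02, 0.01],
            folds=10,
        )
        assert select_r_star(curve) == 3  # 0.92+0.02 >= 0.93; 0.85+0.01 < 0.93

    def test_strictly_increasing_zero_sd_selects_max(self):
        curve = AccuracyCurve([1, 2, 3], [0.7, 0.8, 0.9], [0.0, 0.0, 0.0], folds=5)
        assert select_r_star(curve) == 3

    def test_constant_curve_selects_one(self):
        curve = AccuracyCurve([1, 2, 3], [0.8, 0.8, 0.8], [0.0, 0.0, 0.0], folds=5)
        assert select_r_star(curve) == 1

    def test_never_exceeds_argmax(self, rng):
        for _ in range(50):
            mean = rng.uniform(0.5, 1.0, 8)
            sd = rng.uniform(0.0, 0.1, 8)
            curve = AccuracyCurve(np.arange(1, 9), mean, sd, folds=10)
            r_star = select_r_star(curve)
            assert r_star <= int(np.argmax(mean)) + 1
            if np.all(sd == 0) and np.sum(mean == mean.max()) == 1:
                assert r_star == int(np.argmax(mean)) + 1


class TestAccuracyCurve:
    def test_strong_single_feature_curve_shape(self, rng):
        n = 60
        y = rng.random(n) < 0.5
        X = np.vstack(
            [np.where(y, 1.0, -1.0) + rng.normal(0, 0.3, n)]
            + [rng.normal(size=n) for _ in range(5)]
        )
        ds = _dataset(X, y)
        curve = accuracy_curve(ds, r_max=4, k=5, seed=1, pool_size=None)
        assert curve.mean[0] >= 0.9  # one real feature carries the signal
        assert curve.mean.max() - curve.mean[0] <= 0.08  # flat beyond small r

    def test_null_labels_give_chance_accuracy(self, rng):
        n = 80
        y = rng.random(n) < 0.5
        X = rng.normal(size=(6, n))
        ds = _dataset(X, y)
        curve = accuracy_curve(ds, r_max=3, k=5, seed=2, pool_size=None)
        majority = max(y.mean(), 1 - y.mean())
        band = 3 * np.sqrt(majority * (1 - majority) / n)
        assert np.all(curve.mean <= majority + band + 0.05)

    def test_hand_traced_two_fold_run(self, rng):
        """k=2 toy set reproduces a manual trace of the procedure."""
        y = np.array([False, True, False, True, False, True, False, True])
        X = np.vstack(
            [
                np.where(y, 1.0, -1.0) + rng.normal(0, 0.2, 8),
                rng.normal(size=8),
            ]
        )
        ds = _dataset(X, y)
        curve = accuracy_curve(ds, r_max=2, k=2, seed=5, pool_size=None)
        # manual trace: same folds, same per-fold ranking, same SVM
        from mrmrsvm import mrmr_rank

        folds = stratified_folds(ds, 2, seed=5)
        expected = np.zeros((2, 2))
        for i, fold in enumerate(folds):
            test_idx = np.asarray([ds.matrix.sample_ids.index(s) for s in fold])
            mask = np.ones(8, dtype=bool)
            mask[test_idx] = False
            tr = ds.subset_samples(np.flatnonzero(mask))
            te = ds.subset_samples(test_idx)
            ranking = mrmr_rank(tr, top_k=2)
            for r in (1, 2):
                mod = train_linear_svm(tr, ranking.top(r))
                pred = mod.predict(te.matrix.to_frame()) == "positive"
                expected[i, r - 1] = np.mean(pred == te.y)
        np.testing.assert_allclose(curve.fold_accuracies, expected)
        np.testing.assert_allclose(curve.mean, expected.mean(axis=0))
        np.testing.assert_allclose(curve.sd, expected.std(axis=0, ddof=1))

    def test_heldout_fold_never_influences_ranking(self, rng):
        """Corrupting a held-out fold must not change that fold's ranking."""
        n = 40
        y = rng.random(n) < 0.5
        X = np.vstack([np.where(y, 0.8, -0.8) + rng.normal(0, 0.5, n)]
                      + [rng.normal(size=n) for _ in range(4)])
        ds = _dataset(X, y)
        folds = stratified_folds(ds, 4, seed=11)
        curve = accuracy_curve(ds, r_max=3, k=4, seed=11, pool_size=None)
        # corrupt fold 0's values wildly
        idx0 = [ds.matrix.sample_ids.index(s) for s in folds[0]]
        Xc = X.copy()
        Xc[:, idx0] = rng.normal(50, 100, size=(5, len(idx0)))
        dsc = _dataset(Xc, y)
        curve_c = accuracy_curve(dsc, r_max=3, k=4, seed=11, pool_size=None)
        assert curve.fold_rankings[0].order == curve_c.fold_rankings[0].order


class TestFitResults:
    def test_end_to_end_determinism(self, zscored_dataset):
        est = FeatureSelectingSVM(zscored_dataset, r_max=3, n_folds=5, pool_size=None)
        a, b = est.fit(seed=4), est.fit(seed=4)
        assert a.r_star == b.r_star
        assert a.model.features == b.model.features
        np.testing.assert_array_equal(a.model.weights, b.model.weights)
        np.testing.assert_array_equal(a.curve.fold_accuracies, b.curve.fold_accuracies)

    def test_single_separating_feature_gives_r_star_one(self, rng):
        n = 100
        y = rng.random(n) < 0.5
        X = np.vstack(
            [np.where(y, 1.0, -1.0) + rng.normal(0, 0.05, n)]
            + [rng.normal(size=n) for _ in range(9)]
        )
        res = FeatureSelectingSVM(_dataset(X, y), r_max=5, n_folds=5,
                                  pool_size=None).fit(seed=0)
        assert res.r_star == 1
        assert res.model.features == ["F0"]

    def test_requires_standardized_stage(self, tiny_cohort):
        ds, _ = tiny_cohort
        with pytest.raises(ValueError, match="stage"):
            FeatureSelectingSVM(ds)  # raw cohort must be normalized first

    def test_summary_mentions_selected_probes(self, zscored_dataset):
        res = FeatureSelectingSVM(
            zscored_dataset, r_max=2, n_folds=5, pool_size=None
        ).fit(seed=1)
        text = res.summary()
        assert f"r* = {res.r_star}" in text
        for f in res.model.features:
            assert f in text

    def test_from_dataframe_constructor(self, rng):
        import pandas as pd

        n = 30
        y = np.arange(n) % 2 == 0
        X = np.vstack([np.where(y, 1.0, -1.0) + rng.normal(0, 0.3, n),
                       rng.normal(size=n)])
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        df = pd.DataFrame(X, index=["G1", "G2"], columns=[f"s{j}" for j in range(n)])
        labels = {f"s{j}": bool(y[j]) for j in range(n)}
        est = FeatureSelectingSVM.from_dataframe(df, labels, r_max=2, n_folds=5,
                                                 pool_size=None)
        res = est.fit(seed=0)
        assert res.model.features[0] == "G1"
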