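"""Label merging, stratified folds, random search and the cascade itself."""

import numpy as np
import pandas as pd
import pytest

from cnclust.cascade import (
    MERGED_LEVELS,
    PAIRS,
    BoostConfig,
    HyperparameterSpace,
    ModelError,
    merge_labels,
    predict,
    predict_flat10,
    random_search,
    stratified_folds,
    train_cascade,
    train_flat10,
)
from cnclust.regions import FeatureMatrix

SMALL = BoostConfig(n_estimators=20, max_depth=3)


def _separable_features(n_per_class=12, n_features=12, seed=0, scale=5.0):
    """Linearly separable toy features: class c has mean scale*e_c-ish."""
    rng = np.random.default_rng(seed)
    rows, ids, labels = [], [], {}
    centers = rng.normal(size=(10, n_features)) * scale
    i = 0
    for cls in range(1, 11):
        for _ in range(n_per_class):
            rows.append(centers[cls - 1] + rng.normal(size=n_features))
            ids.append(f"s{i}")
            labels[f"s{i}"] = cls
            i += 1
    df = pd.DataFrame(np.vstack(rows), index=ids,
                      columns=[f"1:{j * 10 + 1}-{j * 10 + 10}" for j in range(n_features)])
    return FeatureMatrix(df, scaled=True), labels


class TestMergeLabels:
    @pytest.mark.parametrize("label,merged", [
        (1, "1/5"), (5, "1/5"), (3, "3/8"), (8, "3/8"),
        (4, "4/7"), (7, "4/7"), (9, "9/10"), (10, "9/10"),
        (2, "2"), (6, "6"),
    ])
    def test_published_pairing(self, label, merged):
        assert merge_labels(label) == merged

    @pytest.mark.parametrize("bad", [0, 11, "x", None])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ModelError):
            merge_labels(bad)


class TestStratifiedFolds:
    def test_balanced_classes_exact_split(self):
        y = np.repeat(np.arange(5), 10)
        folds = stratified_folds(y, k=5, seed=0)
        for cls in range(5):
            counts = np.bincount(folds[y == cls], minlength=5)
            assert (counts == 2).all()

    def test_partition_of_all_indices(self):
        y = np.repeat(np.arange(3), 20)
        folds = stratified_folds(y, k=5, seed=1)
        assert ((folds >= 0) & (folds < 5)).all()
        assert len(folds) == 60

    def test_unbalanced_counts_differ_by_at_most_one(self):
        y = np.array([0] * 7 + [1] * 11 + [2] * 13)
        folds = stratified_folds(y, k=5, seed=2)
        for cls in range(3):
            counts = np.bincount(folds[y == cls], minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_class_smaller_than_k_rejected(self):
        y = np.array([0] * 3 + [1] * 10)
        with pytest.raises(ModelError, match="class 0"):
            stratified_folds(y, k=5, seed=0)

    def test_seed_determinism(self):
        y = np.repeat(np.arange(4), 9)
        a = stratified_folds(y, k=3, seed=7)
        b = stratified_folds(y, k=3, seed=7)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, stratified_folds(y, k=3, seed=8))


@pytest.fixture(scope="module")
def xy():
    fm, labels = _separable_features(n_per_class=8, n_features=6, seed=1)
    y = np.array([labels[s] for s in fm.sample_ids])
    merged = np.array([MERGED_LEVELS.index(merge_labels(c)) for c in y])
    folds = stratified_folds(merged, k=3, seed=0)
    return fm.values, merged, folds


class TestRandomSearch:
    SPACE = HyperparameterSpace(n_estimators=(10, 30), max_depth=(2, 4))

    def test_single_trial_returns_it(self, xy):
        x, y, folds = xy
        best, trials = random_search(x, y, folds, self.SPACE, 1, "logloss", seed=0)
        assert len(trials) == 1
        assert best == trials[0].config

    def test_seed_reproducibility(self, xy):
        x, y, folds = xy
        best1, t1 = random_search(x, y, folds, self.SPACE, 3, "logloss", seed=5)
        best2, t2 = random_search(x, y, folds, self.SPACE, 3, "logloss", seed=5)
        assert best1 == best2
        assert [t.mean_objective for t in t1] == [t.mean_objective for t in t2]
        assert [t.config for t in t1] == [t.config for t in t2]

    def test_prefix_minimum_property(self, xy):
        x, y, folds = xy
        _, t_short = random_search(x, y, folds, self.SPACE, 2, "logloss", seed=9)
        _, t_long = random_search(x, y, folds, self.SPACE, 5, "logloss", seed=9)
        assert [t.config for t in t_long[:2]] == [t.config for t in t_short]
        assert min(t.mean_objective for t in t_long) <= min(t.mean_objective for t in t_short)

    def test_binary_rmse_objective(self):
        fm, labels = _separable_features(n_per_class=10, n_features=4, seed=2)
        y10 = np.array([labels[s] for s in fm.sample_ids])
        mask = (y10 == 1) | (y10 == 5)
        yb = (y10[mask] == 5).astype(int)
        folds = stratified_folds(yb, k=2, seed=0)
        best, trials = random_search(fm.values[mask], yb, folds, self.SPACE, 2, "rmse", seed=0)
        assert all(0 <= t.mean_objective <= 1 for t in trials)


@pytest.fixture(scope="module")
def fixture_data():
    return _separable_features(seed=3)


@pytest.fixture(scope="module")
def bundle(fixture_data):
    fm, labels = fixture_data
    return train_cascade(fm, labels, multiclass_config=SMALL,
                         binary_configs=None, seed=0)


class TestTraining:

    def test_bundle_structure(self, bundle):
        assert set(bundle.binary_models) == {"1/5", "3/8", "4/7", "9/10"}
        assert len(bundle.regions) == 12

    def test_training_recall_on_separable_data(self, fixture_data, bundle):
        fm, labels = fixture_data
        pred = predict(bundle, fm)
        truth = np.array([labels[s] for s in pred.index])
        assert (pred["final_label"].to_numpy() == truth).mean() == 1.0

    def test_flat10_training_recall(self, fixture_data):
        fm, labels = fixture_data
        model = train_flat10(fm, labels, config=SMALL, seed=0)
        pred = predict_flat10(model, fm)
        truth = np.array([labels[s] for s in pred.index])
        assert (pred["final_label"].to_numpy() == truth).mean() == 1.0
        probs = pred[[f"ic{c}" for c in range(1, 11)]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_missing_class_rejected(self, fixture_data):
        fm, labels = fixture_data
        partial = {s: l for s, l in labels.items() if l != 6}
        sub = FeatureMatrix(fm.df.loc[list(partial)], scaled=True)
        with pytest.raises(ModelError, match="missing IntClust"):
            train_cascade(sub, partial, multiclass_config=SMALL)

    def test_unscaled_features_rejected(self, fixture_data, bundle):
        fm, _ = fixture_data
        with pytest.raises(ModelError, match="scaled"):
            predict(bundle, FeatureMatrix(fm.df, scaled=False))

    def test_feature_dimension_mismatch_rejected(self, fixture_data, bundle):
        fm, _ = fixture_data
        narrow = FeatureMatrix(fm.df.iloc[:, :5], scaled=True)
        with pytest.raises(ModelError, match="mismatch"):
            predict(bundle, narrow)


@pytest.fixture(scope="module")
def setup():
    fm, labels = _separable_features(seed=4)
    bundle = train_cascade(fm, labels, multiclass_config=SMALL, seed=0)
    return fm, labels, bundle, predict(bundle, fm)


class TestPrediction:

    def test_composed_probs_sum_to_one(self, setup):
        _, _, _, pred = setup
        probs = pred[[f"ic{c}" for c in range(1, 11)]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)

    def test_final_label_consistent_with_merge(self, setup):
        _, _, _, pred = setup
        for _, row in pred.iterrows():
            assert merge_labels(int(row["final_label"])) == row["merged_label"]

    def test_singleton_class_skips_binary_model(self, setup):
        _, _, _, pred = setup
        singles = pred[pred["merged_label"].isin(["2", "6"])]
        assert singles["binary_prob"].isna().all()

    def test_pair_resolution_threshold(self, setup):
        _, _, _, pred = setup
        paired = pred[~pred["merged_label"].isin(["2", "6"])]
        for _, row in paired.iterrows():
            lo, hi = (int(v) for v in row["merged_label"].split("/"))
            expected = hi if row["binary_prob"] >= 0.5 else lo
            assert int(row["final_label"]) == expected

    def test_composed_argmax_matches_cascade_on_separable_data(self, setup):
        _, _, _, pred = setup
        probs = pred[[f"ic{c}" for c in range(1, 11)]].to_numpy()
        np.testing.assert_array_equal(probs.argmax(axis=1) + 1,
                                      pred["final_label"].to_numpy())

    def test_prediction_deterministic(self, setup):
        fm, _, bundle, pred = setup
        again = predict(bundle, fm)
        pd.testing.assert_frame_equal(pred, again)

    def test_masked_features_do_not_crash(self, setup):
        fm, labels, bundle, pred = setup
        rng = np.random.default_rng(0)
        df = fm.df.copy()
        mask = rng.random(df.shape) < 0.1
        df.values[mask] = np.nan
        masked_pred = predict(bundle, FeatureMatrix(df, scaled=True))
        assert masked_pred["final_label"].between(1, 10).all()
        changed = (masked_pred["final_label"] != pred["final_label"]).mean()
        assert changed < 0.5  # region-feature cohorts are checked at <= 10%
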