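"""Cross-validation harness, LOGO folds and permutation importance."""

import numpy as np
import pandas as pd
import pytest

from phyllopan import classify, simulate
from phyllopan.classify import CVConfig
from phyllopan.io_formats import MetadataTable


COLUMNS = ["isolate_id", "genus", "species", "source", "year", "cluster"]


def meta_of(sources):
    rows = [(f"i{k}", "-", "-", s, "-", "-") for k, s in enumerate(sources)]
    df = pd.DataFrame(rows, columns=COLUMNS).set_index("isolate_id")
    return MetadataTable(df)


class TestLabels:
    def test_leaf_is_one_everything_else_zero(self):
        meta = meta_of(["leaf", "soil", "water", "leaf"])
        assert list(classify.make_labels(meta, "leaf")) == [1, 0, 0, 1]

    def test_empty_metadata(self):
        meta = meta_of([])
        assert classify.make_labels(meta, "leaf").size == 0

    def test_missing_isolate_rejected(self):
        meta = meta_of(["leaf"])
        with pytest.raises(ValueError):
            classify.make_labels(meta, "leaf", isolates=["i0", "ghost"])


class TestRepeatedStratifiedCV:
    def separable_data(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        signal = np.repeat(y[:, None] * 5.0, 5, axis=1)
        X = np.hstack([signal, rng.poisson(2, size=(n, 20))])
        return X.astype(float), y

    def test_perfect_feature_scores_one(self):
        X, y = self.separable_data()
        cfg = CVConfig(seed=1, n_repeats=2)
        mean_acc, sd_acc, _ = classify.repeated_stratified_cv(X, y, cfg)
        assert mean_acc == 1.0 and sd_acc == 0.0

    def test_stratification_within_one_item(self):
        X, y = self.separable_data(n=50)
        from sklearn.model_selection import RepeatedStratifiedKFold
        splitter = RepeatedStratifiedKFold(n_splits=5, n_repeats=2,
                                           random_state=0)
        frac = y.mean()
        for _, test in splitter.split(X, y):
            n_pos = y[test].sum()
            assert abs(n_pos - frac * len(test)) <= 1

    def test_determinism_same_seed(self):
        X, y = self.separable_data()
        cfg = CVConfig(seed=7, n_repeats=2)
        _, _, t1 = classify.repeated_stratified_cv(X, y, cfg)
        _, _, t2 = classify.repeated_stratified_cv(X, y, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_small_class_suggests_smaller_k(self):
        X = np.zeros((6, 2))
        y = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="smaller k"):
            classify.repeated_stratified_cv(X, y, CVConfig(n_splits=5))


class TestLogoCV:
    def test_no_leakage_and_one_genus_per_fold(self):
        matrix, meta = simulate.make_separable_panel(seed=0, n_genera=3,
                                                     n_per_genus=8,
                                                     n_noise_ogs=30)
        cfg = CVConfig(seed=0)
        X = classify.feature_matrix(matrix, cfg)
        y = classify.make_labels(meta, "leaf", isolates=matrix.isolate_ids)
        groups = meta.table["genus"].to_numpy()
        results, _, _ = classify.logo_cv(X, y, groups, cfg)
        assert [r.held_out_group for r in results] == ["Genus0", "Genus1",
                                                       "Genus2"]
        assert all(r.n_test == 8 for r in results)

    def test_single_class_test_set_reports_missing_auc(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        y = np.array([1] * 4 + [0] * 4 + [0] * 4)
        groups = np.array(["a"] * 8 + ["b"] * 4)  # group b is pure class 0
        results, _, _ = classify.logo_cv(X, y, groups, CVConfig(seed=0))
        by_group = {r.held_out_group: r for r in results}
        assert by_group["b"].auc is None
        assert by_group["a"].auc is not None

    def test_two_groups_constant_classifier_majority(self):
        # all-zero features force a majority-vote model
        X = np.zeros((10, 3))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        groups = np.array(["a"] * 5 + ["b"] * 5)
        results, _, _ = classify.logo_cv(X, y, groups, CVConfig(seed=0))
        for r in results:
            test_y = y[groups == r.held_out_group]
            train_y = y[groups != r.held_out_group]
            majority = int(train_y.mean() > 0.5)
            assert r.accuracy == pytest.approx((test_y == majority).mean())


class TestPermutationImportance:
    def fitted(self, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([1] * 20 + [0] * 20)
        X = np.hstack([
            y[:, None] * 4.0 + rng.normal(0, 0.3, size=(40, 1)),  # signal
            rng.normal(size=(40, 5)),                              # noise
            np.full((40, 1), 3.0),                                 # constant
        ])
        model = classify.make_classifier("rf", seed)
        model.fit(X, y)
        return model, X, y

    def test_planted_signal_ranks_first(self):
        model, X, y = self.fitted()
        table = classify.permutation_importance(
            model, X, y, feature_ids=["signal"] + [f"n{i}" for i in range(5)]
            + ["const"], seed=1)
        assert table.loc[0, "feature"] == "signal"
        assert table.loc[0, "importance"] > 0
        noise = table[table["feature"] != "signal"]["importance"]
        assert (noise.abs() < 0.1).all()

    def test_constant_feature_importance_exactly_zero(self):
        model, X, y = self.fitted()
        table = classify.permutation_importance(model, X, y, seed=1)
        const = table[table["feature"] == "f6"]
        assert const["importance"].iloc[0] == 0.0

    def test_same_seed_identical_ranking(self):
        model, X, y = self.fitted()
        t1 = classify.permutation_importance(model, X, y, seed=3)
        t2 = classify.permutation_importance(model, X, y, seed=3)
        pd.testing.assert_frame_equal(t1, t2)


class TestRegistry:
    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError, match="registered"):
            classify.make_classifier("gbm", 0)

    def test_feature_transforms(self, tiny_matrix):
        presence = classify.feature_matrix(tiny_matrix,
                                           CVConfig(transform="presence"))
        assert set(np.unique(presence)) <= {0.0, 1.0}
        logged = classify.feature_matrix(tiny_matrix,
                                         CVConfig(transform="log1p"))
        assert logged.max() == pytest.approx(np.log1p(3))
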