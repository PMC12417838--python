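"""Feature assembly, splitting, cross-validation, the subspace-kNN ensemble,
the cubic SVM and evaluation reports."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import KNeighborsClassifier

from ecogpipe import (FEATURE_COLUMNS, KnnSubspaceEnsemble, SplitSpec,
                      assemble_features, collapse_labels, cross_validate,
                      evaluate, make_model, split_train_test)
from ecogpipe.classify import APERIODIC_COLUMNS, PERIODIC_COLUMNS


def _blocks(n_channels=8, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"ch{i:02d}" for i in range(n_channels)]
    bp = pd.DataFrame(rng.uniform(0.1, 5.0, (n_channels, 12)),
                      index=ids, columns=PERIODIC_COLUMNS)
    bp.index.name = "channel_id"
    ap = pd.DataFrame(rng.uniform(0.5, 3.0, (n_channels, 7)),
                      index=ids, columns=APERIODIC_COLUMNS)
    ap.index.name = "channel_id"
    meta = pd.DataFrame({
        "channel_id": ids,
        "patient_id": ["P1"] * (n_channels // 2) + ["P2"] * (n_channels - n_channels // 2),
        "label": (["tumoral", "close_peritumoral", "far_peritumoral", "healthy"]
                  * n_channels)[:n_channels],
    })
    return bp, ap, meta


def _blobs(n_per_class=40, n_features=38, spread=0.05, seed=0):
    """Well-separated 4-class Gaussian blobs in feature space."""
    rng = np.random.default_rng(seed)
    labels = ["tumoral", "close_peritumoral", "far_peritumoral", "healthy"]
    X, y = [], []
    for k, lab in enumerate(labels):
        center = np.zeros(n_features)
        center[k % n_features] = 1.0
        center[(k + 9) % n_features] = -1.0
        X.append(center + spread * rng.standard_normal((n_per_class, n_features)))
        y += [lab] * n_per_class
    return np.vstack(X), np.array(y, dtype=object)


class TestAssembleFeatures:
    def test_complete_inventory_is_38_columns(self):
        bp, ap, meta = _blocks()
        table = assemble_features(bp, ap, meta)
        feature_cols = [c for c in table.columns
                        if c not in ("channel_id", "patient_id", "label")]
        assert len(feature_cols) == 38
        assert feature_cols == FEATURE_COLUMNS

    def test_periodic_half_alone_is_24_columns(self):
        bp, _, meta = _blocks()
        table = assemble_features(bp, None, meta)
        feature_cols = [c for c in table.columns
                        if c not in ("channel_id", "patient_id", "label")]
        assert len(feature_cols) == 24

    def test_normalized_half_in_unit_interval(self):
        bp, ap, meta = _blocks()
        table = assemble_features(bp, ap, meta)
        norm_cols = [c for c in table.columns if c.endswith("_norm")]
        assert len(norm_cols) == 19
        assert table[norm_cols].to_numpy().min() >= 0.0
        assert table[norm_cols].to_numpy().max() <= 1.0 + 1e-12

    def test_identical_channels_identical_rows(self):
        bp, ap, meta = _blocks(4)
        bp.iloc[1] = bp.iloc[0]
        ap.iloc[1] = ap.iloc[0]
        meta.loc[1, "patient_id"] = meta.loc[0, "patient_id"]
        table = assemble_features(bp, ap, meta)
        a = table.loc[0, FEATURE_COLUMNS].to_numpy(dtype=float)
        b = table.loc[1, FEATURE_COLUMNS].to_numpy(dtype=float)
        np.testing.assert_array_equal(a, b)

    def test_missing_feature_rows_excluded(self):
        bp, ap, meta = _blocks(6)
        ap.loc["ch02", "slope_40_60"] = np.nan
        table = assemble_features(bp, ap, meta)
        assert "ch02" not in set(table["channel_id"])
        assert len(table) == 5


class TestSplit:
    @staticmethod
    def _cohort_table(counts):
        rows = []
        for lab, n in counts.items():
            rows += [lab] * n
        return pd.DataFrame({"label": rows, "x": np.arange(len(rows), dtype=float)})

    def test_reference_cohort_split_sizes(self):
        table = self._cohort_table({"tumoral": 121, "close_peritumoral": 243,
                                    "far_peritumoral": 210, "healthy": 134})
        assert len(table) == 708
        train, test = split_train_test(table, SplitSpec(seed=0))
        assert (len(train), len(test)) == (496, 212)

    def test_small_split_seven_three(self):
        table = self._cohort_table({"a": 5, "b": 5})
        train, test = split_train_test(table, SplitSpec(seed=1))
        assert (len(train), len(test)) == (7, 3)

    def test_stratified_preserves_class_proportions(self):
        counts = {"tumoral": 121, "close_peritumoral": 243,
                  "far_peritumoral": 212, "healthy": 134}
        table = self._cohort_table(counts)
        train, _ = split_train_test(table, SplitSpec(seed=3))
        for lab, n in counts.items():
            got = (train["label"] == lab).sum()
            assert abs(got - 0.7 * n) <= 1.0

    def test_disjoint_and_exhaustive(self):
        table = self._cohort_table({"a": 30, "b": 20})
        train, test = split_train_test(table, SplitSpec(seed=5))
        assert not set(train["x"]) & set(test["x"])
        assert set(train["x"]) | set(test["x"]) == set(table["x"])

    def test_same_seed_same_split(self):
        table = self._cohort_table({"a": 30, "b": 20})
        t1, _ = split_train_test(table, SplitSpec(seed=9))
        t2, _ = split_train_test(table, SplitSpec(seed=9))
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_class_in_train_raises(self):
        table = self._cohort_table({"a": 40, "b": 1})
        spec = SplitSpec(train_fraction=0.5, stratified=False, seed=0)
        with pytest.raises(ValueError, match="stratified"):
            for seed in range(50):  # some permutation puts 'b' in test
                spec.seed = seed
                split_train_test(table, spec)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.5)


class TestCrossValidate:
    def test_separable_classes_perfect_folds(self):
        X, y = _blobs(20)
        cv = cross_validate(X, y, "knn_ensemble", k=5, seed=0,
                            param_grid=[{"k_neighbors": 3}])
        assert cv["fold_scores"] == [1.0] * 5

    def test_permuted_labels_score_at_chance(self):
        X, y = _blobs(150, seed=4)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        cv = cross_validate(X, y_perm, "knn_ensemble", k=5, seed=0,
                            param_grid=[{"k_neighbors": 7}])
        assert cv["mean_accuracy"] == pytest.approx(0.25, abs=0.05)

    def test_same_seed_identical_outcome(self):
        X, y = _blobs(15, spread=0.8, seed=2)
        cv1 = cross_validate(X, y, "svm", k=5, seed=11)
        cv2 = cross_validate(X, y, "svm", k=5, seed=11)
        assert cv1 == cv2

    def test_folds_exceeding_class_count_rejected(self):
        X, y = _blobs(3)
        with pytest.raises(ValueError, match="fold"):
            cross_validate(X, y, "svm", k=5, seed=0)


class TestKnnSubspaceEnsemble:
    def test_single_full_space_learner_equals_plain_knn(self):
        X, y = _blobs(25, spread=0.6, seed=3)
        ens = KnnSubspaceEnsemble(n_learners=1, subspace_dim=38,
                                  k_neighbors=5, seed=0).fit(X, y)
        plain = KNeighborsClassifier(n_neighbors=5).fit(X, y)
        Xq = X + 0.1 * np.random.default_rng(1).standard_normal(X.shape)
        np.testing.assert_array_equal(ens.predict(Xq), plain.predict(Xq))

    def test_vote_counts_sum_to_learner_count(self):
        X, y = _blobs(10)
        ens = KnnSubspaceEnsemble(n_learners=30, subspace_dim=19,
                                  k_neighbors=3, seed=0).fit(X, y)
        counts = ens.vote_counts(X[:7])
        np.testing.assert_array_equal(counts.sum(axis=1), 30)

    def test_subspaces_have_requested_dimension(self):
        X, y = _blobs(10)
        ens = KnnSubspaceEnsemble(n_learners=30, subspace_dim=19,
                                  k_neighbors=3, seed=0).fit(X, y)
        assert len(ens.subspaces_) == 30
        assert all(len(s) == 19 and len(np.unique(s)) == 19
                   for s in ens.subspaces_)

    def test_separable_test_f1_high(self):
        X, y = _blobs(40, seed=6)
        table = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        table["label"] = y
        train, test = split_train_test(table, SplitSpec(seed=0))
        for kind in ("knn_ensemble", "svm"):
            model = make_model(kind, seed=0)
            model.fit(train[FEATURE_COLUMNS].to_numpy(), train["label"].to_numpy())
            rep = evaluate(test["label"].to_numpy(),
                           model.predict(test[FEATURE_COLUMNS].to_numpy()))
            assert rep.f1_macro >= 0.95

    def test_excessive_neighbors_rejected(self):
        X, y = _blobs(3)
        with pytest.raises(ValueError):
            KnnSubspaceEnsemble(k_neighbors=100).fit(X, y)

    def test_deterministic_given_seed(self):
        X, y = _blobs(15, spread=0.7, seed=8)
        p1 = KnnSubspaceEnsemble(seed=5).fit(X, y).predict(X)
        p2 = KnnSubspaceEnsemble(seed=5).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestEvaluate:
    def test_perfect_predictions_all_metrics_one(self):
        y = np.array(["a", "b", "a", "b", "c"], dtype=object)
        rep = evaluate(y, y)
        assert rep.precision_macro == rep.recall_macro == rep.f1_macro == 1.0
        assert rep.accuracy == 1.0
        np.testing.assert_array_equal(np.diag(rep.confusion.to_numpy()),
                                      rep.per_class["support"].to_numpy())

    def test_hand_computed_binary_confusion(self):
        # TP=3, FP=1, FN=1, TN=5 for class "pos"
        y_true = ["pos"] * 4 + ["neg"] * 6
        y_pred = ["pos", "pos", "pos", "neg", "pos"] + ["neg"] * 5
        rep = evaluate(y_true, y_pred)
        assert rep.per_class.loc["pos", "precision"] == pytest.approx(0.75)
        assert rep.per_class.loc["pos", "recall"] == pytest.approx(0.75)
        assert rep.per_class.loc["pos", "f1"] == pytest.approx(0.75)
        assert rep.confusion.loc["pos", "pos"] == 3
        assert rep.confusion.loc["neg", "pos"] == 1

    def test_row_sums_equal_class_supports(self, rng):
        y_true = rng.choice(["a", "b", "c"], 60)
        y_pred = rng.choice(["a", "b", "c"], 60)
        rep = evaluate(y_true, y_pred)
        np.testing.assert_array_equal(rep.confusion.sum(axis=1).to_numpy(),
                                      rep.per_class["support"].to_numpy())

    def test_collapse_tumoral_vs_nontumoral(self):
        labels = ["tumoral", "close_peritumoral", "far_peritumoral", "healthy"]
        out, keep = collapse_labels(labels, "tumoral_vs_nontumoral")
        assert keep.all()
        assert list(out) == ["tumoral", "non_tumoral", "non_tumoral", "non_tumoral"]

    def test_collapse_tumoral_vs_healthy_drops_peritumoral(self):
        labels = ["tumoral", "close_peritumoral", "far_peritumoral", "healthy"]
        out, keep = collapse_labels(labels, "tumoral_vs_healthy")
        assert list(np.asarray(out)[keep]) == ["tumoral", "healthy"]
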