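"""Fold construction, metrics, confusion normalization, experiment runs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import confusion_matrix as sk_confusion

import squeaksort as sq
from squeaksort.evaluate import (
    SplitPlan,
    compute_metrics,
    make_folds,
    normalize_confusion,
    run_experiment,
)
from squeaksort.features import FEATURE_NAMES
from squeaksort.models import MlpSpec, RfSpec


def counting_metrics_oracle(y_true, y_pred, n_classes):
    """Per-sample counting oracle for precision/recall/accuracy."""
    tp = np.zeros(n_classes)
    fp = np.zeros(n_classes)
    fn = np.zeros(n_classes)
    correct = 0
    for t, p in zip(y_true, y_pred):
        if t == p:
            tp[t] += 1
            correct += 1
        else:
            fp[p] += 1
            fn[t] += 1
    prec = [tp[c] / (tp[c] + fp[c]) for c in range(n_classes) if tp[c] + fp[c] > 0]
    rec = [tp[c] / (tp[c] + fn[c]) for c in range(n_classes) if tp[c] + fn[c] > 0]
    return np.mean(prec), np.mean(rec), correct / len(y_true)


class TestMakeFolds:
    def test_ten_folds_partition_all_samples(self):
        labels = np.repeat(["a", "b"], 50)
        folds = make_folds(labels, SplitPlan(seed=0))
        tests = [f.test for f in folds]
        assert all(len(t) == 10 for t in tests)
        assert sorted(np.concatenate(tests).tolist()) == list(range(100))

    def test_stratified_counts_per_fold(self):
        labels = np.repeat(["A", "B"], 50)
        for fold in make_folds(labels, SplitPlan(seed=1)):
            vals, counts = np.unique(labels[fold.test], return_counts=True)
            assert counts.tolist() == [5, 5]

    def test_train_val_test_disjoint(self):
        labels = np.repeat(list("abcd"), 30)
        for fold in make_folds(labels, SplitPlan(seed=2)):
            assert not set(fold.train) & set(fold.val)
            assert not set(fold.train) & set(fold.test)
            assert not set(fold.val) & set(fold.test)

    def test_seed_determinism(self):
        labels = np.repeat(["x", "y"], 40)
        a = make_folds(labels, SplitPlan(seed=9))
        b = make_folds(labels, SplitPlan(seed=9))
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.test, fb.test)
            np.testing.assert_array_equal(fa.train, fb.train)

    def test_small_class_rejected_under_stratification(self):
        labels = np.array(["a"] * 5 + ["b"] * 50)
        with pytest.raises(ValueError, match="stratified"):
            make_folds(labels, SplitPlan(n_folds=10))

    def test_holdout_scheme_is_80_20(self):
        labels = np.repeat(["a", "b"], 50)
        folds = make_folds(labels, SplitPlan(scheme="holdout", seed=0))
        assert len(folds) == 10
        assert all(len(f.test) == 20 for f in folds)


class TestComputeMetrics:
    def test_worked_two_class_example(self):
        m = compute_metrics(np.array([[8, 2], [3, 7]]))
        assert m.accuracy == pytest.approx(0.75)
        assert m.per_class_precision[0] == pytest.approx(8 / 11)
        assert m.per_class_recall[0] == pytest.approx(0.8)

    def test_perfect_and_worst_cases(self):
        perfect = compute_metrics(np.diag([5, 5]))
        assert perfect.precision == perfect.recall == perfect.accuracy == 1.0
        worst = compute_metrics(np.array([[0, 5], [5, 0]]))
        assert worst.accuracy == 0.0

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((3, 3)))

    @settings(max_examples=1000, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)),
            min_size=1, max_size=40,
        )
    )
    def test_matches_counting_oracle(self, data):
        y_true = np.array([t for t, _ in data])
        y_pred = np.array([p for _, p in data])
        cm = sk_confusion(y_true, y_pred, labels=range(4))
        m = compute_metrics(cm)
        prec, rec, acc = counting_metrics_oracle(y_true, y_pred, 4)
        assert m.precision == pytest.approx(prec)
        assert m.recall == pytest.approx(rec)
        assert m.accuracy == pytest.approx(acc)


class TestNormalizeConfusion:
    def test_row_division(self):
        out = normalize_confusion(np.array([[8, 2], [3, 7]]))
        np.testing.assert_allclose(out, [[0.8, 0.2], [0.3, 0.7]])

    def test_diagonal_matrix_becomes_identity(self):
        np.testing.assert_allclose(
            normalize_confusion(np.diag([4, 9, 2])), np.eye(3)
        )

    def test_zero_rows_preserved(self):
        out = normalize_confusion(np.array([[0, 0], [1, 1]]))
        np.testing.assert_allclose(out, [[0, 0], [0.5, 0.5]])
        assert out[1].sum() == pytest.approx(1.0)


@pytest.fixture(scope="module")
def feature_table():
    rng = np.random.default_rng(0)
    n = 160
    classes = np.array(["upward", "downward", "short", "flat"])
    y = np.repeat(classes, n // 4)
    X = rng.normal(0, 1, (n, 20)) + 4 * np.arange(4).repeat(n // 4)[:, None]
    table = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    table["class"] = y
    table["strain"] = np.where(rng.random(n) < 0.5, "WT", "KO")
    return table


class TestRunExperiment:
    def test_majority_baseline_accuracy(self):
        """A constant classifier scores exactly the majority fraction."""
        from sklearn.dummy import DummyClassifier

        rng = np.random.default_rng(1)
        y = np.array(["a"] * 80 + ["b"] * 20)
        cm = sk_confusion(y, DummyClassifier(strategy="most_frequent")
                          .fit(np.zeros((100, 1)), y).predict(np.zeros((100, 1))),
                          labels=["a", "b"])
        assert compute_metrics(cm).accuracy == pytest.approx(0.8)

    def test_separable_experiment_near_perfect(self, feature_table):
        reports = run_experiment(
            feature_table, MlpSpec(),
            plan=SplitPlan(n_folds=5, seed=0), balance="none",
        )
        mean, _ = reports["entire"].accuracy
        assert mean > 0.9
        # aggregate accuracy equals the mean of fold accuracies
        fold_accs = [m.accuracy for m in reports["entire"].fold_metrics]
        assert mean == pytest.approx(np.mean(fold_accs))
        # row-normalized confusion rows sum to 1
        norm = reports["entire"].confusion_normalized
        np.testing.assert_allclose(norm.sum(axis=1), 1.0, atol=1e-9)

    def test_scoped_runs_and_empty_scope_error(self, feature_table):
        reports = run_experiment(
            feature_table, RfSpec(n_trees=20),
            plan=SplitPlan(n_folds=2, seed=0), scopes=("KO", "WT"),
        )
        assert set(reports) == {"KO", "WT"}
        wt_only = feature_table[feature_table["strain"] == "WT"]
        with pytest.raises(ValueError, match="no samples"):
            run_experiment(
                wt_only, RfSpec(n_trees=5),
                plan=SplitPlan(n_folds=2, seed=0), scopes=("KO",),
            )

    def test_drop_class_shrinks_confusion(self, feature_table):
        reports = run_experiment(
            feature_table, RfSpec(n_trees=10),
            plan=SplitPlan(n_folds=2, seed=0),
            drop_classes=("short",),
        )
        assert reports["entire"].confusion.shape == (3, 3)
        assert "short" not in reports["entire"].class_names

    def test_cnn_experiment_image_path(self):
        """The CNN route consumes images and produces a full report."""
        import squeaksort as sq
        from squeaksort.features import extract_feature_table, render_call_images
        from squeaksort.models import CnnSpec

        ds = sq.generate_dataset(sq.balanced_profile(8, seed=2))
        table = extract_feature_table(ds.calls)
        images = render_call_images(ds.calls, shape=(24, 32), mode="resize")
        reports = run_experiment(
            table,
            CnnSpec(input_shape=(24, 32), epochs=1, batch_size=16),
            images=images,
            plan=SplitPlan(n_folds=2, val_fraction=0.0, seed=0),
            balance="class_weights",
        )
        r = reports["entire"]
        assert r.confusion.shape == (10, 10)
        assert r.confusion.sum() == 80

    def test_no_leakage_from_test_outliers(self, feature_table):
        """Standardizer and oversampler see only training rows: replacing a
        test fold's rows by huge outliers leaves training stats unchanged."""
        from squeaksort.features import FeatureStandardizer

        y = feature_table["class"].to_numpy()
        X = feature_table[list(FEATURE_NAMES)].to_numpy()
        folds = make_folds(y, SplitPlan(n_folds=4, seed=0))
        fold = folds[0]
        base = FeatureStandardizer().fit(X[fold.train])
        X_poisoned = X.copy()
        X_poisoned[fold.test] += 1e6
        poisoned = FeatureStandardizer().fit(X_poisoned[fold.train])
        np.testing.assert_array_equal(base.mean_, poisoned.mean_)
        np.testing.assert_array_equal(base.scale_, poisoned.scale_)
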