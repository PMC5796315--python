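"""z-layout encoding, K-means, metric arithmetic, and cross-validation."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfecg import synth
from zfecg.classify import (
    CNNBackboneUnavailable,
    cnn_adapter,
    crossvalidate,
    encode_dataset,
    encode_zlayout,
    evaluate,
    f1_from_precision_recall,
    kmeans_fit,
    kmeans_predict,
    map_clusters_to_labels,
    register_adapter,
    truncate_square,
)


class TestTruncateSquare:
    @pytest.mark.parametrize("n,keep,side", [(3000, 2916, 54), (2916, 2916, 54),
                                             (3050, 3025, 55), (4, 4, 2)])
    def test_largest_leading_square(self, n, keep, side):
        seg = np.arange(n, dtype=float)
        out, s = truncate_square(seg)
        assert (len(out), s) == (keep, side)
        np.testing.assert_array_equal(out, seg[:keep])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            truncate_square(np.zeros(3))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(n=st.integers(min_value=4, max_value=5000))
    def test_matches_brute_force_over_squares(self, n):
        out, side = truncate_square(np.zeros(n))
        best = max(k * k for k in range(1, n + 1) if k * k <= n)
        assert len(out) == best and side * side == best


class TestZLayout:
    def test_ramp_fills_row_major(self):
        img = encode_zlayout(np.arange(2916, dtype=float))
        assert img.side == 54
        assert img.matrix[0, 0] == 0.0
        assert img.matrix[53, 53] == 255.0
        flat = img.matrix.ravel()
        assert np.all(np.diff(flat) >= 0)
        # sample k sits at [k // side, k % side]
        assert img.matrix[1, 0] == pytest.approx(54 / 2915 * 255)

    def test_constant_segment_is_mid_grey(self):
        img = encode_zlayout(np.full(64, 3.7))
        np.testing.assert_array_equal(img.matrix, 128.0)

    def test_positive_affine_invariance(self):
        rng = np.random.default_rng(0)
        seg = rng.normal(size=2916)
        a = encode_zlayout(seg)
        b = encode_zlayout(2.5 * seg + 17.0)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-9)

    def test_non_square_length_rejected(self):
        with pytest.raises(ValueError, match="perfect square"):
            encode_zlayout(np.zeros(3000))

    def test_png_export_is_8bit_greyscale(self, tmp_path):
        from PIL import Image

        img = encode_zlayout(np.arange(2916, dtype=float))
        path = img.to_png(tmp_path / "seg.png")
        loaded = Image.open(path)
        assert loaded.mode == "L" and loaded.size == (54, 54)


class TestKMeans:
    def blobs(self, seed=0, n=30, d=5, sep=20.0):
        rng = np.random.default_rng(seed)
        centers = np.eye(3, d) * sep
        X = np.vstack([rng.normal(c, 1.0, size=(n, d)) for c in centers])
        y = np.repeat([0, 1, 2], n)
        return X, y

    def test_separated_blobs_recovered_perfectly(self):
        X, y = self.blobs()
        model = kmeans_fit(X, k=3, seed=0)
        mapping = map_clusters_to_labels(model.assignments, y, classes=[0, 1, 2])
        pred = np.array([mapping[j] for j in model.assignments])
        assert np.mean(pred == y) == 1.0

    def test_k_equals_n_gives_zero_wcss(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 3))
        model = kmeans_fit(X, k=6, seed=0, n_init=1)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(set(model.assignments.tolist())) == 6

    def test_wcss_monotone_nonincreasing(self):
        X, _ = self.blobs(seed=2, sep=3.0)
        model = kmeans_fit(X, k=3, seed=3, n_init=1)
        hist = model.inertia_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_fixed_point_stable_on_duplicated_dataset(self):
        X, _ = self.blobs(seed=4)
        model = kmeans_fit(X, k=3, seed=5)
        dup = np.vstack([X, X])
        again = kmeans_fit(dup, k=3, init=model.centroids)
        np.testing.assert_allclose(again.centroids, model.centroids, atol=1e-9)

    def test_deterministic_per_seed(self):
        X, _ = self.blobs(seed=6, sep=2.0)
        a = kmeans_fit(X, k=3, seed=7)
        b = kmeans_fit(X, k=3, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_matches_sklearn_on_fixture(self):
        # Independent cross-check: same data, both should find the blob
        # partition (compare partitions, not label ids).
        from sklearn.cluster import KMeans

        X, y = self.blobs(seed=8)
        ours = kmeans_fit(X, k=3, seed=0)
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        for labels in (ours.assignments, sk.labels_):
            for blob in range(3):
                assert len(set(labels[y == blob].tolist())) == 1
        assert ours.inertia == pytest.approx(sk.inertia_, rel=1e-6)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.zeros((2, 2)), k=3)

    def test_predict_nearest_centroid(self):
        X, y = self.blobs(seed=9)
        model = kmeans_fit(X, k=3, seed=0)
        pred = kmeans_predict(model, X)
        np.testing.assert_array_equal(pred, model.assignments)


class TestClusterLabelMapping:
    def test_majority_vote(self):
        assignments = np.array([0] * 10)
        labels = np.array(["AVB"] * 9 + ["SA"])
        mapping = map_clusters_to_labels(assignments, labels, ["AVB", "SA", "STE"], k=1)
        assert mapping[0] == "AVB"

    def test_pure_clusters_bijective(self):
        assignments = np.array([0, 0, 1, 1, 2, 2])
        labels = np.array(["AVB", "AVB", "SA", "SA", "STE", "STE"])
        mapping = map_clusters_to_labels(assignments, labels, ["AVB", "SA", "STE"])
        assert sorted(mapping.values()) == ["AVB", "SA", "STE"]

    def test_tie_breaks_to_earliest_class(self):
        assignments = np.zeros(4, dtype=int)
        labels = np.array(["SA", "SA", "AVB", "AVB"])
        mapping = map_clusters_to_labels(assignments, labels, ["AVB", "SA"], k=1)
        assert mapping[0] == "AVB"


class TestEvaluate:
    def test_perfect_predictions(self):
        y = ["AVB", "SA", "STE"] * 4
        res = evaluate(y, y, ["AVB", "SA", "STE"])
        assert res.average_accuracy == 1.0
        assert res.macro_precision == res.macro_recall == res.macro_f1 == 1.0
        np.testing.assert_array_equal(np.diag(res.confusion), [4, 4, 4])

    def test_f1_identity(self):
        assert f1_from_precision_recall(0.78, 0.70) == pytest.approx(0.74, abs=0.005)
        assert f1_from_precision_recall(0.0, 0.0) == 0.0

    def test_counts_match_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(5)
        classes = ["a", "b", "c", "d"]
        truth = rng.choice(classes, size=200)
        pred = rng.choice(classes, size=200)
        res = evaluate(pred, truth, classes)
        for i, c in enumerate(classes):
            tp = sum(1 for t, p in zip(truth, pred) if t == c and p == c)
            fp = sum(1 for t, p in zip(truth, pred) if t != c and p == c)
            fn = sum(1 for t, p in zip(truth, pred) if t == c and p != c)
            tn = sum(1 for t, p in zip(truth, pred) if t != c and p != c)
            row = res.per_class.iloc[i]
            assert (row["tp"], row["fp"], row["fn"], row["tn"]) == (tp, fp, fn, tn)
            assert tp + fp + fn + tn == 200
        # confusion conservation
        assert res.confusion.sum() == 200
        np.testing.assert_array_equal(
            res.confusion.sum(axis=1),
            [np.sum(truth == c) for c in classes],
        )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import confusion_matrix, precision_score, recall_score

        rng = np.random.default_rng(6)
        classes = ["AVB", "SA", "STE"]
        truth = rng.choice(classes, size=150)
        pred = rng.choice(classes, size=150)
        res = evaluate(pred, truth, classes)
        np.testing.assert_array_equal(
            res.confusion, confusion_matrix(truth, pred, labels=classes)
        )
        assert res.macro_precision == pytest.approx(
            precision_score(truth, pred, average="macro", zero_division=0)
        )
        assert res.macro_recall == pytest.approx(
            recall_score(truth, pred, average="macro")
        )

    def test_class_absent_from_truth_excluded_with_note(self):
        res = evaluate(["a", "a"], ["a", "a"], ["a", "b"])
        assert any("absent" in n for n in res.notes)
        assert res.macro_recall == 1.0  # only class 'a' contributes

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["a"], ["a", "b"], ["a", "b"])


@pytest.fixture(scope="module")
def dataset():
    # Default experiment size: 60 segments per class.
    segments, labels = synth.segment_dataset(n_per_class=60, seed=2)
    X, _ = encode_dataset(segments)
    return X, labels


class TestCrossValidate:

    def test_each_sample_tests_exactly_once(self, dataset):
        X, y = dataset
        res = crossvalidate(X, y, folds=10, seed=0)
        seen = np.concatenate([f["test_indices"] for f in res.folds])
        assert sorted(seen.tolist()) == list(range(len(y)))
        assert res.confusion.sum() == len(y)

    def test_separable_dataset_high_macro_f1(self, dataset):
        X, y = dataset
        res = crossvalidate(X, y, folds=10, seed=0)
        assert res.macro_f1 >= 0.95

    def test_seeded_rerun_identical(self, dataset):
        X, y = dataset
        a = crossvalidate(X, y, folds=10, seed=3)
        b = crossvalidate(X, y, folds=10, seed=3)
        assert a.to_dict() == b.to_dict()

    def test_too_few_samples_per_class_rejected(self, dataset):
        X, y = dataset
        sel = slice(55, 75)  # 5 samples of the first class, 15 of the next
        with pytest.raises(ValueError, match="per class"):
            crossvalidate(X[sel], y[sel], folds=10, seed=0)

    def test_internal_f1_identity_holds(self, dataset):
        X, y = dataset
        res = crossvalidate(X, y, folds=10, seed=1)
        expected = f1_from_precision_recall(res.macro_precision, res.macro_recall)
        assert res.macro_f1 == pytest.approx(expected, abs=1e-12)


class TestCNNAdapter:
    def test_plugin_disabled_without_backbone(self):
        with pytest.raises(CNNBackboneUnavailable, match="plugin disabled"):
            cnn_adapter([], [], backbone="inception_v3")

    def test_registered_adapter_is_used(self):
        register_adapter("toy", lambda images, labels: "handle")
        try:
            assert cnn_adapter([], [], backbone="toy") == "handle"
        finally:
            from zfecg import classify

            classify._ADAPTERS.pop("toy", None)

    def test_kmeans_path_runs_without_plugin(self):
        segments, labels = synth.segment_dataset(n_per_class=10, seed=3)
        X, _ = encode_dataset(segments)
        res = crossvalidate(X, labels, folds=10, seed=0)
        assert res.n_samples == 30
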