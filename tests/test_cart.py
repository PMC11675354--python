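"""CART internals: impurity, splits, training, prediction, serialization."""

import numpy as np
import pytest

import steatoquant as sq
from steatoquant.cart import (
    FAT,
    NON_FAT,
    CartTree,
    best_split,
    feature_matrix,
    gini_impurity,
    train_cart,
)


def brute_force_best_split(column, labels):
    """Oracle: enumerate every midpoint between distinct sorted values."""
    xs = sorted(set(column))
    n = len(column)

    def gini(subset):
        if not subset:
            return 0.0
        classes = set(subset)
        return 1.0 - sum((subset.count(c) / len(subset)) ** 2 for c in classes)

    parent = gini(list(labels))
    best_thr, best_dec = None, 0.0
    for lo, hi in zip(xs[:-1], xs[1:]):
        thr = (lo + hi) / 2.0
        left = [l for x, l in zip(column, labels) if x <= thr]
        right = [l for x, l in zip(column, labels) if x > thr]
        dec = parent - (len(left) * gini(left) + len(right) * gini(right)) / n
        if dec > best_dec + 1e-12:
            best_dec, best_thr = dec, thr
    return best_thr, best_dec


class TestGini:
    def test_pure_is_zero(self):
        assert gini_impurity(["a"] * 7) == 0.0

    def test_balanced_two_classes(self):
        assert gini_impurity(["a", "a", "b", "b"]) == pytest.approx(0.5)

    def test_three_one_split(self):
        assert gini_impurity(["a", "a", "a", "b"]) == pytest.approx(0.375)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity([])


class TestBestSplit:
    def test_perfectly_separable(self):
        thr, dec = best_split([1, 2, 10, 11], ["A", "A", "B", "B"])
        assert thr == pytest.approx(6.0)
        assert dec == pytest.approx(0.5)

    def test_constant_column_no_split(self):
        thr, dec = best_split([3, 3, 3, 3], ["A", "B", "A", "B"])
        assert thr is None
        assert dec == 0.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 15))
            col = list(rng.integers(0, 6, size=n).astype(float))
            labels = list(rng.choice(["x", "y"], size=n))
            thr, dec = best_split(col, labels)
            o_thr, o_dec = brute_force_best_split(col, labels)
            assert dec == pytest.approx(o_dec, abs=1e-9)
            if o_thr is not None:
                assert thr == pytest.approx(o_thr)

    def test_root_split_matches_sklearn(self):
        """Independent check of the split criterion against scikit-learn."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(11)
        for seed in range(10):
            x = rng.normal(size=(40, 3))
            y = np.where(x[:, seed % 3] + 0.3 * rng.normal(size=40) > 0, FAT, NON_FAT)
            if len(set(y)) < 2:
                continue
            ours = train_cart(sq.TrainingSet(x, y), max_depth=1, min_samples_leaf=1)
            ref = DecisionTreeClassifier(max_depth=1, random_state=0).fit(x, y)
            assert ours.root.feature == ref.tree_.feature[0]
            # scikit-learn quantizes inputs to float32 before splitting
            assert ours.root.threshold == pytest.approx(
                ref.tree_.threshold[0], rel=1e-5
            )


class TestTrainPredict:
    def _separable(self):
        x = np.array([[0.0, 1], [1, 1], [2, 1], [10, 1], [11, 1], [12, 1]])
        y = np.array([NON_FAT] * 3 + [FAT] * 3)
        return sq.TrainingSet(x, y)

    def test_separable_depth_one_perfect(self):
        tree = train_cart(self._separable(), max_depth=5, min_samples_leaf=1)
        assert tree.depth() == 1
        assert list(tree.predict(self._separable().features)) == list(
            self._separable().labels
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_cart(sq.TrainingSet(np.zeros((4, 2)), np.array([FAT] * 4)))

    def test_deterministic_serialization(self):
        ts = self._separable()
        a = train_cart(ts).to_json()
        b = train_cart(ts).to_json()
        assert a == b

    def test_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 6))
        y = np.where(x[:, 2] > 0.2, FAT, NON_FAT)
        tree = train_cart(sq.TrainingSet(x, y), min_samples_leaf=2)
        path = tmp_path / "model.json"
        tree.save(path)
        back = CartTree.load(path)
        grid = rng.normal(size=(100, 6))
        assert list(tree.predict(grid)) == list(back.predict(grid))

    def test_feature_scale_robustness(self):
        """No pre-normalization needed: per-column rescaling is harmless."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=(80, 6))
        y = np.where(x[:, 1] - 0.5 * x[:, 4] > 0, FAT, NON_FAT)
        test = rng.normal(size=(50, 6))
        base = train_cart(sq.TrainingSet(x, y)).predict(test)
        for col, factor in [(1, 1000.0), (4, 0.001)]:
            xs = x.copy()
            xs[:, col] *= factor
            ts_scaled = test.copy()
            ts_scaled[:, col] *= factor
            scaled = train_cart(sq.TrainingSet(xs, y)).predict(ts_scaled)
            assert list(base) == list(scaled)

    def test_depth_zero_tree_predicts_majority(self):
        x = np.array([[0.0], [1.0], [2.0]])
        tree = train_cart(
            sq.TrainingSet(x, np.array([FAT, FAT, NON_FAT])), max_depth=0,
            min_samples_leaf=1,
        )
        assert tree.depth() == 0
        assert tree.predict_one([123.0]) == FAT

    def test_leaf_tie_goes_to_non_fat(self):
        x = np.array([[0.0], [0.0]])
        tree = train_cart(
            sq.TrainingSet(x, np.array([FAT, NON_FAT])), max_depth=3,
            min_samples_leaf=1,
        )
        assert tree.predict_one([0.0]) == NON_FAT

    def test_arity_mismatch_rejected(self, trained_tree):
        with pytest.raises(ValueError, match="arity"):
            trained_tree.predict_one([1.0, 2.0])

    def test_batch_predict_equals_map_of_single(self, trained_tree):
        rng = np.random.default_rng(1)
        batch = np.abs(rng.normal(size=(20, 6)))
        assert list(trained_tree.predict(batch)) == [
            trained_tree.predict_one(fv) for fv in batch
        ]


class TestTrainingSetFromTruth:
    def test_truth_labels(self, default_phantom, default_candidates):
        _, truth = default_phantom
        ts = sq.make_training_set(default_candidates, truth)
        n_fat = int((ts.labels == FAT).sum())
        assert n_fat == len(truth.fat_objects)

    def test_labels_invariant_to_order(self, default_phantom, default_candidates):
        _, truth = default_phantom
        fwd = sq.make_training_set(default_candidates, truth)
        rev = sq.make_training_set(default_candidates[::-1], truth)
        assert list(fwd.labels) == list(rev.labels[::-1])

    def test_no_overlap_is_non_fat(self, default_phantom, default_candidates):
        _, truth = default_phantom
        # candidate far from every object: synthesize one over empty truth
        import dataclasses

        c = dataclasses.replace(default_candidates[0])
        empty = dataclasses.replace(truth, label_raster=np.zeros_like(truth.label_raster))
        ts = sq.make_training_set([c], empty)
        assert list(ts.labels) == [NON_FAT]

    def test_empty_candidates_rejected(self, default_phantom):
        _, truth = default_phantom
        with pytest.raises(ValueError):
            sq.make_training_set([], truth)

    def test_phantom_classifier_accuracy(self, trained_tree):
        """Held-out phantom: collagen/size/intensity features separate classes."""
        img, truth = sq.generate_phantom(sq.PhantomSpec(seed=302))
        tissue = sq.tissue_mask(img)
        cands = sq.detect_candidates(img, tissue)
        labels = sq.make_training_set(cands, truth).labels
        pred = trained_tree.predict(feature_matrix(cands))
        assert (pred == labels).mean() >= 0.95
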