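import numpy as np
import pytest

from bnaf import prediction_pipeline as pp
from bnaf.antifragility import DifferenceCurve
from bnaf.robustness_classification import CLASS_ORDER, RobustnessClass


def separable_dataset(counts=(100, 60, 40, 20), sigma=0.05, seed=0):
    """Four well-separated class-mean curves plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    means = rng.normal(0, 1, (4, 30))
    X = np.vstack([means[i] + rng.normal(0, sigma, (c, 30)) for i, c in enumerate(counts)])
    y = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    groups = np.array([f"net{i % 7}" for i in range(len(y))], dtype=object)
    return pp.FeatureDataset(X, y, groups)


class TestBuildDataset:
    def test_three_rows(self):
        grid = np.linspace(0.1, 1.0, 30)
        curves = [
            (DifferenceCurve(grid, np.full(30, float(i))), CLASS_ORDER[i], f"n{i}")
            for i in range(3)
        ]
        data = pp.build_dataset(curves)
        assert data.features.shape == (3, 30)
        assert list(data.labels) == [0, 1, 2]
        assert list(data.groups) == ["n0", "n1", "n2"]

    def test_empty_input_is_valid(self):
        data = pp.build_dataset([])
        assert len(data) == 0

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError):
            pp.build_dataset([(np.zeros(29), CLASS_ORDER[0], "x")])

    def test_synthetic_cohort_group_sizes(self):
        rng = np.random.default_rng(1)
        rows = [
            (rng.normal(0, 1, 30), CLASS_ORDER[int(rng.integers(4))], f"net{i:02d}")
            for i in range(20)
            for _ in range(50)
        ]
        data = pp.build_dataset(rows)
        assert len(data) == 1000
        _, counts = np.unique(data.groups.astype(str), return_counts=True)
        assert set(counts) == {50}


class TestOversample:
    def test_balanced_input_unchanged_by_smote(self):
        data = separable_dataset(counts=(30, 30, 30, 30))
        out = pp.oversample(data, "SMOTE", seed=0)
        assert len(out) == len(data)
        assert np.array_equal(out.features, data.features)

    def test_smote_equalizes_counts(self):
        data = separable_dataset(counts=(100, 40, 30, 10))
        out = pp.oversample(data, "SMOTE", seed=0)
        assert all(n == 100 for n in out.class_counts().values())

    def test_adasyn_approximately_equalizes(self):
        data = separable_dataset(counts=(100, 40, 30, 10))
        out = pp.oversample(data, "ADASYN", seed=0)
        counts = list(out.class_counts().values())
        assert max(counts) == 100 and min(counts) == 100

    def test_original_rows_retained_with_labels(self):
        data = separable_dataset(counts=(50, 20, 15, 8))
        out = pp.oversample(data, "SMOTE", seed=3)
        assert np.array_equal(out.features[: len(data)], data.features)
        assert np.array_equal(out.labels[: len(data)], data.labels)

    def test_synthetic_points_lie_on_same_class_segments(self):
        data = separable_dataset(counts=(40, 12, 30, 25), sigma=0.3, seed=5)
        for method in ("SMOTE", "ADASYN"):
            out = pp.oversample(data, method, seed=7)
            for row, label in zip(out.features[len(data):], out.labels[len(data):]):
                Xc = data.features[data.labels == label]
                # on a segment between two originals a & b: row = a + u*(b-a)
                diffs = row[None, :] - Xc
                a_idx = np.argmin(np.linalg.norm(diffs, axis=1))
                found = False
                for b in Xc:
                    seg = b - Xc[a_idx]
                    denom = seg @ seg
                    if denom == 0:
                        continue
                    u = (row - Xc[a_idx]) @ seg / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                        Xc[a_idx] + u * seg, row, atol=1e-8
                    ):
                        found = True
                        break
                assert found

    def test_tiny_class_rejected_with_hint(self):
        data = separable_dataset(counts=(50, 20, 15, 1))
        with pytest.raises(ValueError, match="duplicat"):
            pp.oversample(data, "SMOTE", seed=0)

    def test_seeded_reproducibility(self):
        data = separable_dataset(counts=(60, 30, 20, 10))
        a = pp.oversample(data, "ADASYN", seed=11)
        b = pp.oversample(data, "ADASYN", seed=11)
        assert np.array_equal(a.features, b.features)


class TestBuildCNN:
    def test_simple_layer_counts(self):
        model = pp.build_cnn("simple")
        assert model.n_conv_layers == 2 and model.n_pool_layers == 1

    def test_complex_layer_counts(self):
        model = pp.build_cnn("complex")
        assert model.n_conv_layers == 4 and model.n_pool_layers == 2

    def test_forward_pass_is_probability_vector(self):
        for arch in ("simple", "complex"):
            model = pp.build_cnn(arch, seed=1)
            proba = model.predict_proba(np.zeros((1, 30)))
            assert proba.shape == (1, 4)
            assert proba.sum() == pytest.approx(1.0)
            assert np.all(proba >= 0)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            pp.build_cnn("deep")

    def test_training_learns_separable_data(self):
        data = separable_dataset(counts=(40, 40, 40, 40))
        model = pp.build_cnn("simple", seed=0)
        model.fit(data.features, data.labels, epochs=12, batch_size=32, seed=0)
        assert (model.predict(data.features) == data.labels).mean() > 0.9

    def test_weight_round_trip(self):
        model = pp.build_cnn("simple", seed=2)
        clone = pp.build_cnn("simple", seed=99)
        clone.set_weights(model.get_weights())
        x = np.random.default_rng(0).normal(0, 1, (5, 30))
        assert np.allclose(model.predict_proba(x), clone.predict_proba(x))


class TestEvaluate:
    class _Perfect:
        def predict_proba(self, X):
            # label encoded in feature 0
            out = np.zeros((len(X), 4))
            out[np.arange(len(X)), X[:, 0].astype(int)] = 1.0
            return out

    class _Random:
        def __init__(self, seed):
            self.rng = np.random.default_rng(seed)

        def predict_proba(self, X):
            p = self.rng.random((len(X), 4))
            return p / p.sum(axis=1, keepdims=True)

    def _labelled(self, counts, seed=0):
        y = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
        X = np.zeros((len(y), 30))
        X[:, 0] = y
        return pp.FeatureDataset(X, y, np.zeros(len(y), dtype=object))

    def test_perfect_predictions(self):
        data = self._labelled((20, 15, 10, 5))
        rep = pp.evaluate(self._Perfect(), data)
        assert rep.accuracy == 1.0
        assert np.allclose(rep.confusion, np.eye(4))
        assert all(v == pytest.approx(1.0) for v in rep.per_class_ap.values())

    def test_confusion_rows_sum_to_one(self):
        data = self._labelled((20, 15, 10, 5))
        rep = pp.evaluate(self._Random(0), data)
        assert np.allclose(rep.confusion.sum(axis=1), 1.0, atol=1e-9)

    def test_random_scores_ap_near_prevalence(self):
        counts = (120, 80, 40, 20)
        data = self._labelled(counts)
        total = sum(counts)
        aps = {c: [] for c in CLASS_ORDER}
        for seed in range(30):
            rep = pp.evaluate(self._Random(seed), data)
            for c in CLASS_ORDER:
                aps[c].append(rep.per_class_ap[c])
        for i, c in enumerate(CLASS_ORDER):
            prevalence = counts[i] / total
            mean_ap = np.mean(aps[c])
            spread = 3 * np.std(aps[c]) / np.sqrt(30) + 0.02
            assert abs(mean_ap - prevalence) < max(spread, 0.05)

    def test_empty_test_rejected(self):
        with pytest.raises(ValueError):
            pp.evaluate(self._Perfect(), pp.FeatureDataset(
                np.empty((0, 30)), np.empty(0, dtype=int), np.empty(0, dtype=object)
            ))


class TestRandomBaselineAP:
    def test_published_prevalences(self):
        counts = {"nrne": 4992, "nre": 20603, "rne": 8788, "re": 2617}
        ap = pp.random_baseline_ap(counts)
        assert round(ap["nrne"], 3) == 0.135
        assert round(ap["nre"], 3) == 0.557
        assert round(ap["rne"], 3) == 0.238
        assert round(ap["re"], 3) == 0.071

    def test_two_balanced_classes(self):
        assert pp.random_baseline_ap({"a": 50, "b": 50}) == {"a": 0.5, "b": 0.5}

    def test_single_class(self):
        assert pp.random_baseline_ap({"a": 9}) == {"a": 1.0}

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            pp.random_baseline_ap({"a": 0})


SMALL_GRID = [
    pp.HyperparameterSet(32, "SMOTE", "simple", epochs=6),
    pp.HyperparameterSet(64, "ADASYN", "simple", epochs=6),
]


class TestNestedCrossValidation:
    def test_full_grid_has_12_sets(self):
        grid = pp.default_grid()
        assert len(grid) == 12
        assert len({(h.batch_size, h.balancing, h.architecture) for h in grid}) == 12
        assert all(h.epochs == 128 for h in grid)

    def test_outer_folds_partition_training_portion(self):
        data = separable_dataset()
        best, reports, details = pp.nested_cross_validation(
            data, SMALL_GRID, seed=0
        )
        train_idx = set(details["train_indices"].tolist())
        test_idx = set(details["test_indices"].tolist())
        assert train_idx.isdisjoint(test_idx)
        assert train_idx | test_idx == set(range(len(data)))
        assert len(test_idx) == round(0.25 * len(data))

    def test_selection_is_deterministic_in_seed(self):
        data = separable_dataset()
        b1, _, d1 = pp.nested_cross_validation(data, SMALL_GRID, seed=5)
        b2, _, d2 = pp.nested_cross_validation(data, SMALL_GRID, seed=5)
        assert b1 == b2
        assert d1["auc_final"] == d2["auc_final"]

    def test_separable_fixture_beats_majority_prevalence(self):
        data = separable_dataset(sigma=0.05, seed=2)
        best, reports, details = pp.nested_cross_validation(data, SMALL_GRID, seed=1)
        test = data.subset(details["test_indices"])
        majority = max(np.bincount(test.labels)) / len(test)
        mean_acc = np.mean([r.accuracy for r in reports])
        assert mean_acc > majority
        micro_baseline = (np.bincount(test.labels, minlength=4) / len(test)).mean()
        assert np.mean([r.micro_ap for r in reports]) > micro_baseline

    def test_missing_class_rejected(self):
        data = separable_dataset(counts=(50, 40, 30, 0))
        with pytest.raises(ValueError):
            pp.nested_cross_validation(data, SMALL_GRID, seed=0)
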