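"""LOOCV harness, metrics against a brute-force oracle, PCA, reporting."""

import numpy as np
import pytest

import homecage as hc
from homecage.evaluation import FoldPrediction, _stratified_fold_subset, compute_metrics


class OneNearestNeighbourStub:
    """Memorising 1-NN: predicts the label of the closest training row."""

    def fit(self, x, y, class_weight=None):
        self.x, self.y = np.asarray(x), np.asarray(y)
        return self

    def predict(self, x):
        d = np.linalg.norm(np.asarray(x)[:, None, :] - self.x[None], axis=2)
        return self.y[d.argmin(axis=1)]


class MajorityStub:
    """Predicts the (weight-adjusted) majority training class."""

    def fit(self, x, y, class_weight=None):
        vals, counts = np.unique(y, return_counts=True)
        self.c = int(vals[counts.argmax()])
        return self

    def predict(self, x):
        return np.full(len(x), self.c)


def brute_force_metrics(y_true, y_pred, k=3):
    """Independent counting oracle in plain Python loops."""
    n = len(y_true)
    confusion = [[0] * k for _ in range(k)]
    for t, p in zip(y_true, y_pred):
        confusion[t][p] += 1
    acc = sum(confusion[c][c] for c in range(k)) / n
    precision, recall, f1 = [], [], []
    for c in range(k):
        tp = confusion[c][c]
        fp = sum(confusion[r][c] for r in range(k)) - tp
        fn = sum(confusion[c][r] for r in range(k)) - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(2 * p * r / (p + r) if p + r else 0.0)
    return acc, confusion, precision, recall, f1


def _preds(y_true, y_pred):
    return [
        FoldPrediction(index=i, y_true=int(t), y_pred=int(p))
        for i, (t, p) in enumerate(zip(y_true, y_pred))
    ]


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 1, 2, 0])
        m = compute_metrics(_preds(y, y))
        assert m.accuracy == 1.0
        assert m.macro_precision == m.macro_recall == m.macro_f1 == 1.0
        assert np.array_equal(np.diag(m.confusion), [2, 2, 2])
        assert m.confusion.sum() == 6

    def test_hand_worked_example(self):
        # truth (0,1,2,1), predicted (0,1,1,1): class 2 never predicted
        m = compute_metrics(_preds([0, 1, 2, 1], [0, 1, 1, 1]))
        assert m.accuracy == 0.75
        assert m.per_class_precision[2] == 0.0
        assert m.macro_precision == pytest.approx((1 + 2 / 3 + 0) / 3)

    def test_matches_bruteforce_oracle_on_random_labels(self, rng):
        y_true = rng.integers(0, 3, 1000)
        y_pred = rng.integers(0, 3, 1000)
        m = compute_metrics(_preds(y_true, y_pred))
        acc, confusion, precision, recall, f1 = brute_force_metrics(y_true, y_pred)
        assert m.accuracy == pytest.approx(acc, abs=1e-12)
        assert np.array_equal(m.confusion, confusion)
        assert np.allclose(m.per_class_precision, precision, atol=1e-12)
        assert np.allclose(m.per_class_recall, recall, atol=1e-12)
        assert np.allclose(m.per_class_f1, f1, atol=1e-12)
        assert m.macro_f1 == pytest.approx(np.mean(f1), abs=1e-12)

    def test_macro_f1_is_mean_of_per_class_f1(self, rng):
        m = compute_metrics(_preds(rng.integers(0, 3, 50), rng.integers(0, 3, 50)))
        assert m.macro_f1 == pytest.approx(m.per_class_f1.mean())
        # and generally not the harmonic mean of macro P and macro R
        assert m.macro_f1 <= 1.0

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(_preds([0, 5], [0, 1]))

    def test_invalid_folds_are_surfaced(self):
        preds = _preds([0, 1], [0, 1])
        preds.append(FoldPrediction(index=2, y_true=2, y_pred=None, error="lost a class"))
        with pytest.raises(ValueError, match="invalid fold"):
            compute_metrics(preds)


class TestLoocv:
    def test_prediction_indices_are_a_permutation(self, small_observations):
        preds = hc.loocv(small_observations, lambda s: MajorityStub(), mode="record")
        assert sorted(p.index for p in preds) == list(range(len(small_observations)))

    def test_memorising_model_on_duplicated_points_scores_one(self, rng):
        # every held-out point has an identical twin in the training data
        base = rng.normal(size=(15, 4))
        labels = np.tile(rng.integers(0, 3, 15), 2)
        obs = [
            hc.BinnedObservation(
                f"a{i}", ["naive", "injured", "sham"][labels[i]], 1, 0,
                np.tile(base[i % 15], (5, 1)), int(labels[i]),
            )
            for i in range(30)
        ]
        preds = hc.loocv(obs, lambda s: OneNearestNeighbourStub(), mode="record")
        assert compute_metrics(preds).accuracy == 1.0

    def test_fold_losing_a_class_is_reported_invalid(self):
        obs = []
        for i, (group, label) in enumerate([("naive", 0), ("injured", 1), ("injured", 1)]):
            obs.append(
                hc.BinnedObservation(f"a{i}", group, 1, 0, np.full((3, 4), float(i)), label)
            )
        preds = hc.loocv(obs, lambda s: MajorityStub(), mode="record")
        invalid = [p for p in preds if not p.valid]
        assert len(invalid) == 1 and invalid[0].index == 0
        assert "class" in invalid[0].error

    def test_leakage_sentinel_heldout_perturbation(self, small_observations):
        """Replacing a held-out observation with an extreme constant must not
        move its own fold's standardizer or class weights."""
        import copy

        obs = list(small_observations[:30])
        target = 7
        baseline = hc.loocv(
            obs, lambda s: MajorityStub(), mode="record", capture_fold_state=True
        )
        perturbed_obs = copy.deepcopy(obs)
        perturbed_obs[target].segment[:] = 1e9
        perturbed = hc.loocv(
            perturbed_obs, lambda s: MajorityStub(), mode="record", capture_fold_state=True
        )
        b, p = baseline[target], perturbed[target]
        assert np.array_equal(b.standardizer.mean, p.standardizer.mean)
        assert np.array_equal(b.standardizer.sd, p.standardizer.sd)
        assert b.weights == p.weights

    def test_max_folds_subsample_is_stratified(self, small_observations):
        labels = np.array([o.label for o in small_observations])
        preds = hc.loocv(
            small_observations, lambda s: MajorityStub(), mode="record", max_folds=24, seed=0
        )
        assert len(preds) == 24
        picked = np.array([p.y_true for p in preds])
        for c in (0, 1, 2):
            expected_share = (labels == c).mean()
            assert abs((picked == c).mean() - expected_share) < 0.1

    def test_stratified_subset_allocation_exact(self):
        labels = np.repeat([0, 1, 2], [24, 180, 180])
        idx = _stratified_fold_subset(labels, 90, seed=1)
        assert len(idx) == 90
        picked = labels[idx]
        assert [(picked == c).sum() for c in (0, 1, 2)] == [6, 42, 42]

    def test_sequence_mode_trains_on_standardized_scaleograms(self, small_observations):
        captured = {}

        class Probe(MajorityStub):
            def fit(self, inputs, y, class_weight=None):
                captured["shapes"] = (inputs[0].shape, inputs[1].shape)
                return super().fit(inputs[0].reshape(len(y), -1), y, class_weight)

            def predict(self, inputs):
                return np.zeros(len(inputs[0]), dtype=int)

        obs = small_observations[:20]
        hc.loocv(obs, lambda s: Probe(), mode="sequence", max_folds=1, seed=0)
        seq_shape, scal_shape = captured["shapes"]
        assert seq_shape == (19, 48, 4)
        assert scal_shape == (19, 16, 48, 4)


class TestFixedSplitSmoteReport:
    def test_report_covers_test_partition_only(self, small_observations):
        report = hc.fixed_split_smote_report(
            small_observations, lambda s: hc.make_baseline("random_forest", seed=s), seed=0
        )
        n = len(small_observations)
        assert report.n == pytest.approx(0.15 * n, abs=2)
        assert 0.0 <= report.accuracy <= 1.0

    def test_smote_never_touches_heldout_observations(self, small_observations):
        """Enabling SMOTE must not change which rows are evaluated or their values."""
        captured = {}

        class Probe(MajorityStub):
            def fit(self, x, y, class_weight=None):
                captured.setdefault("train_sizes", []).append(len(y))
                return super().fit(x, y, class_weight)

            def predict(self, x):
                captured.setdefault("test_sets", []).append(np.asarray(x).copy())
                return super().predict(x)

        for use_smote in (False, True):
            hc.fixed_split_smote_report(
                small_observations, lambda s: Probe(), use_smote=use_smote, seed=3
            )
        without, with_smote = captured["test_sets"]
        assert np.array_equal(without, with_smote)
        assert captured["train_sizes"][1] >= captured["train_sizes"][0]
        # after SMOTE the training classes are balanced (equal thirds)
        assert captured["train_sizes"][1] % 3 == 0


class TestPca:
    def test_explained_variance_is_non_increasing(self, rng):
        coords, ev = hc.pca_embedding(rng.normal(size=(40, 4)))
        assert coords.shape == (40, 2)
        assert ev[0] >= ev[1]

    def test_projection_is_mean_centred(self, rng):
        coords, _ = hc.pca_embedding(rng.normal(size=(40, 4)))
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-9)

    def test_two_dimensional_data_reconstructs_exactly(self, rng):
        x = rng.normal(size=(30, 2)) @ np.array([[2.0, 0.3], [0.1, 1.0]])
        coords, ev = hc.pca_embedding(np.column_stack([x, np.zeros((30, 2))]), 2)
        # distances are preserved by a full-rank orthogonal projection
        d_orig = np.linalg.norm(x - x.mean(0), axis=1)
        d_proj = np.linalg.norm(coords, axis=1)
        assert np.allclose(np.sort(d_orig), np.sort(d_proj), atol=1e-9)
        assert ev.sum() == pytest.approx(1.0)

    def test_constant_dataset_rejected(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            hc.pca_embedding(np.ones((10, 4)))


class TestReport:
    def test_table_deterministic_and_row_per_model(self, tmp_path, rng):
        y = rng.integers(0, 3, 40)
        metrics = {name: compute_metrics(_preds(y, y)) for name in ("svm", "rf")}
        t1 = hc.evaluation_report(metrics, out_dir=tmp_path)
        t2 = hc.evaluation_report(metrics)
        assert t1 == t2
        assert len([l for l in t1.splitlines() if l and not l.startswith(("model", "-"))]) == 2
        assert (tmp_path / "report.txt").read_text() == t1
        assert (tmp_path / "confusion_svm.png").exists()

    def test_confusion_rows_sum_to_class_support(self, rng):
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        m = compute_metrics(_preds(y_true, y_pred))
        for c in (0, 1, 2):
            assert m.confusion[c].sum() == (y_true == c).sum()
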