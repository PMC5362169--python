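import numpy as np
import pytest

from sledamage.cohort_select import LabeledSequence, ModelDataset, fit_age_scaler
from sledamage.errors import ConfigurationError, DataError
from sledamage.evaluation import (
    RocCurve,
    cross_validate_rnn,
    hidden_sweep,
    kfold_split,
    roc_curve,
    threshold_table,
)
from sledamage.rnn_core import TrainConfig


def labels_dataset(labels):
    rng = np.random.default_rng(0)
    seqs = [
        LabeledSequence(f"P{i}", rng.normal(size=(3, 2)), int(l))
        for i, l in enumerate(labels)
    ]
    return ModelDataset(seqs, ["a", "b"], {})


class TestKfoldSplit:
    def test_study_group_sizes_partition(self):
        ds = labels_dataset([1] * 38 + [0] * 94)
        split = kfold_split(ds, k=8, seed=0)
        labels = ds.labels
        case_counts = [int((labels[split.test_indices(f)] == 1).sum()) for f in range(8)]
        ctrl_counts = [int((labels[split.test_indices(f)] == 0).sum()) for f in range(8)]
        assert sorted(case_counts) == [4, 4, 5, 5, 5, 5, 5, 5]
        assert sorted(ctrl_counts) == [11, 11, 12, 12, 12, 12, 12, 12]

    def test_k_one_rejected(self):
        with pytest.raises(ConfigurationError):
            kfold_split(labels_dataset([0, 1] * 5), k=1, seed=0)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ConfigurationError):
            kfold_split(labels_dataset([1] * 3 + [0] * 20), k=8, seed=0)

    def test_deterministic(self):
        ds = labels_dataset([0, 1] * 20)
        a = kfold_split(ds, k=4, seed=5)
        b = kfold_split(ds, k=4, seed=5)
        assert np.array_equal(a.assignment, b.assignment)


def concordance_auc(scores, labels):
    """Brute-force pairwise concordance with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestRocCurve:
    def test_three_score_example(self):
        # pairs: (0.9 vs 0.8) concordant, (0.3 vs 0.8) discordant -> 0.5
        assert roc_curve([0.9, 0.8, 0.3], [1, 0, 1]).auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == pytest.approx(1.0)

    def test_all_ties(self):
        assert roc_curve([0.4] * 6, [1, 0, 1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_curve([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(12))
    def test_trapezoid_equals_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_curve(scores, labels).auc == pytest.approx(
            concordance_auc(scores, labels)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(100 + seed)
        scores = np.round(rng.random(60), 2)
        labels = rng.integers(0, 2, 60)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_endpoints_and_monotone(self):
        roc = roc_curve([0.7, 0.5, 0.5, 0.2, 0.9], [1, 0, 1, 0, 1])
        assert (roc.tpr[0], roc.fpr[0]) == (0.0, 0.0)
        assert (roc.tpr[-1], roc.fpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.thresholds) < 0)


class TestThresholdTable:
    def _roc_with_points(self, points):
        thr = np.array([np.inf] + [p[0] for p in points])
        tpr = np.array([0.0] + [p[1] for p in points])
        fpr = np.array([0.0] + [1 - p[2] for p in points])
        return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=0.77)

    def test_reports_exactly_the_qualifying_rows_in_order(self):
        qualifying = [
            (0.486, 0.819, 0.711),
            (0.383, 0.755, 0.711),
            (0.365, 0.745, 0.737),
            (0.358, 0.745, 0.763),
            (0.290, 0.702, 0.763),
            (0.271, 0.702, 0.789),
        ]
        failing = [(0.6, 0.55, 0.9), (0.1, 0.95, 0.4)]
        roc = self._roc_with_points(sorted(qualifying + failing, key=lambda r: -r[0]))
        rows = threshold_table(roc)
        assert [r[0] for r in rows] == [0.486, 0.383, 0.365, 0.358, 0.290, 0.271]
        assert all(se >= 0.7 and sp >= 0.7 for _, se, sp in rows)

    def test_random_classifier_has_empty_table(self):
        diag = [(t, 1 - t, t) for t in (0.8, 0.6, 0.4, 0.2)]  # TPR == FPR
        assert threshold_table(self._roc_with_points(diag)) == []

    def test_zero_floors_return_every_finite_point(self):
        points = [(0.9, 0.2, 0.95), (0.5, 0.6, 0.6), (0.1, 1.0, 0.05)]
        rows = threshold_table(self._roc_with_points(points), 0.0, 0.0)
        assert len(rows) == len(points)


def quick_dataset(n=40, T=4, p=3, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    seqs = []
    for i in range(n):
        label = i % 2
        X = rng.normal(0, 1, size=(T, p))
        if signal:
            X[:, 0] += 2.0 * label
        seqs.append(LabeledSequence(f"P{i}", X, label))
    return ModelDataset(seqs, ["s", "n1", "age"], {"age_index": 2})


FAST = TrainConfig(n_hidden=5, max_epochs=15, seed=0)


class TestCrossValidate:
    def test_every_sequence_scored_once(self):
        res = cross_validate_rnn(quick_dataset(), FAST, k=4, seed=1)
        assert res.scores.shape == (40,)
        assert np.all(np.isfinite(res.scores))

    def test_signal_recovered_on_easy_data(self):
        res = cross_validate_rnn(quick_dataset(), FAST, k=4, seed=1)
        assert res.auc > 0.8

    def test_age_scalers_fit_on_training_part_only(self):
        ds = quick_dataset()
        res = cross_validate_rnn(ds, FAST, k=4, seed=2)
        ai = ds.metadata["age_index"]
        for fold in range(4):
            expected = fit_age_scaler(
                [ds.sequences[i] for i in res.split.train_indices(fold)], ai
            )
            assert res.fold_age_scalers[fold] == pytest.approx(expected)
            # and the held-out sequences really are excluded
            with_test = fit_age_scaler(ds.sequences, ai)
            assert with_test != pytest.approx(res.fold_age_scalers[fold])

    def test_deterministic_given_seed(self):
        a = cross_validate_rnn(quick_dataset(), FAST, k=4, seed=3)
        b = cross_validate_rnn(quick_dataset(), FAST, k=4, seed=3)
        assert np.array_equal(a.scores, b.scores)


class TestHiddenSweep:
    def test_single_size(self):
        out = hidden_sweep(quick_dataset(), sizes=(4,), train_config=FAST, k=4, seed=0)
        assert set(out) == {4}

    def test_empty_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            hidden_sweep(quick_dataset(), sizes=(), k=4, seed=0)

    def test_sizes_share_folds(self):
        out = hidden_sweep(quick_dataset(), sizes=(3, 5), train_config=FAST, k=4, seed=0)
        assert set(out) == {3, 5}
        for auc in out.values():
            assert 0.0 <= auc <= 1.0
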