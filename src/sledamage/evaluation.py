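"""Pooled k-fold validation, ROC/AUC, operating thresholds, hidden-unit sweep.

Validation follows the pooled scheme: the data (cases and controls
separately, so the split is stratified) are cut into k parts; for each part
a fresh network is trained on the other k-1 and scores the held-out part;
all held-out scores are then pooled into a single set before one ROC curve
and one AUC are computed.  Age standardization is re-fitted on each fold's
training part only, so no statistic of a held-out patient ever reaches the
model that scores them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_select import ModelDataset, fit_age_scaler, standardize_ages
from .errors import ConfigurationError, DataError
from .rnn_core import TrainConfig, TrainHistory, score_sequences, sgd_train


@dataclass
class FoldSplit:
    """Stratified assignment of sequence index -> fold in {0..k-1}."""

    assignment: np.ndarray  # (n,) int
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


@dataclass
class RocCurve:
    """ROC points ordered by decreasing threshold, plus the trapezoidal AUC.

    The first point uses an infinite threshold (nothing classified
    positive, TPR = FPR = 0); the last threshold equals the minimum score
    (everything positive, TPR = FPR = 1).  Classification rule:
    score >= threshold is called positive.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CvResult:
    """Pooled out-of-fold scores with their labels and diagnostics."""

    scores: np.ndarray  # one pooled score per sequence, original order
    labels: np.ndarray
    roc: RocCurve
    split: FoldSplit
    fold_histories: list[TrainHistory] = field(default_factory=list)
    fold_age_scalers: list[tuple[float, float]] = field(default_factory=list)

    @property
    def auc(self) -> float:
        return self.roc.auc


def kfold_split(dataset: ModelDataset, k: int = 8, seed: int = 0) -> FoldSplit:
    """Seeded stratified partition; per-class fold sizes differ by <= 1."""
    if k < 2:
        raise ConfigurationError("k must be >= 2 (k = 1 leaves nothing held out)")
    labels = dataset.labels
    assignment = np.empty(len(labels), dtype=int)
    rng = np.random.default_rng(seed)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ConfigurationError(
                f"class {cls} has {idx.size} members, fewer than k={k}"
            )
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(idx.size) % k  # round-robin deal
    return FoldSplit(assignment=assignment, k=k)


def roc_curve(scores, labels) -> RocCurve:
    """ROC over thresholds at every distinct observed score.

    The trapezoidal AUC over these points equals the tie-aware concordance
    probability P(score_pos > score_neg) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.flatnonzero(np.diff(s) != 0)
    cut = np.r_[distinct, s.size - 1]  # last index of each tie block
    tp = np.cumsum(y == 1)[cut]
    fp = np.cumsum(y == 0)[cut]
    thresholds = np.r_[np.inf, s[cut]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def threshold_table(
    roc: RocCurve, min_sensitivity: float = 0.7, min_specificity: float = 0.7
) -> list[tuple[float, float, float]]:
    """Operating points with sensitivity and specificity both above the floor.

    Rows are (threshold, sensitivity, specificity), sorted by decreasing
    threshold; an empty list is a legitimate outcome (e.g. a random
    classifier has no such point).
    """
    rows = []
    for thr, tpr, fpr in zip(roc.thresholds, roc.tpr, roc.fpr):
        sens, spec = float(tpr), float(1.0 - fpr)
        if np.isfinite(thr) and sens >= min_sensitivity and spec >= min_specificity:
            rows.append((float(thr), sens, spec))
    rows.sort(key=lambda r: -r[0])
    return rows


def _fold_seed(master_seed: int, fold: int) -> int:
    child = np.random.SeedSequence(entropy=master_seed, spawn_key=(fold + 1,))
    return int(child.generate_state(1)[0] % (2**31))


def cross_validate_rnn(
    dataset: ModelDataset,
    train_config: TrainConfig,
    k: int = 8,
    seed: int = 0,
    split: FoldSplit | None = None,
) -> CvResult:
    """Pooled k-fold validation of the recurrent model.

    For each fold: re-fit the age scaler on the training part, train a
    network from a fold-specific seed, score the held-out part; pool all
    held-out scores and compute a single ROC/AUC.
    """
    if split is None:
        split = kfold_split(dataset, k=k, seed=seed)
    labels = dataset.labels
    age_index = dataset.metadata.get("age_index")
    pooled = np.full(len(dataset), np.nan)
    histories: list[TrainHistory] = []
    scalers: list[tuple[float, float]] = []
    for fold in range(split.k):
        tr_idx = split.train_indices(fold)
        te_idx = split.test_indices(fold)
        train_seqs = [dataset.sequences[i] for i in tr_idx]
        test_seqs = [dataset.sequences[i] for i in te_idx]
        if age_index is not None:
            mean, sd = fit_age_scaler(train_seqs, age_index)
            scalers.append((mean, sd))
            train_seqs = standardize_ages(train_seqs, age_index, mean, sd)
            test_seqs = standardize_ages(test_seqs, age_index, mean, sd)
        cfg = TrainConfig(**{**train_config.__dict__, "seed": _fold_seed(seed, fold)})
        weights, hist = sgd_train(ModelDataset(train_seqs, dataset.feature_names), cfg)
        histories.append(hist)
        pooled[te_idx] = score_sequences(weights, test_seqs)
    assert not np.isnan(pooled).any()
    roc = roc_curve(pooled, labels)
    return CvResult(
        scores=pooled, labels=labels, roc=roc, split=split,
        fold_histories=histories, fold_age_scalers=scalers,
    )


def per_fold_aucs(result: CvResult) -> list[float]:
    """Diagnostic: AUC computed within each held-out part separately."""
    out = []
    for fold in range(result.split.k):
        idx = result.split.test_indices(fold)
        out.append(roc_curve(result.scores[idx], result.labels[idx]).auc)
    return out


def hidden_sweep(
    dataset: ModelDataset,
    sizes=(50, 100),
    train_config: TrainConfig | None = None,
    k: int = 8,
    seed: int = 0,
) -> dict[int, float]:
    """Pooled AUC per hidden-layer size, on shared folds."""
    sizes = list(sizes)
    if not sizes:
        raise ConfigurationError("sizes must be non-empty")
    base = train_config or TrainConfig()
    split = kfold_split(dataset, k=k, seed=seed)
    out: dict[int, float] = {}
    for n in sizes:
        cfg = TrainConfig(**{**base.__dict__, "n_hidden": int(n)})
        out[int(n)] = cross_validate_rnn(dataset, cfg, k=k, seed=seed, split=split).auc
    return out
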