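"""Static comparison models: logistic regression and a feed-forward network.

Both consume a fixed-length vector per patient built by concatenating the
features of the last L visits of the usable window (the same pre-damage /
pre-horizon window the recurrent model sees).  They are the reference
points for the claim that the damage signal lives in the visit *history*:
when the planted signal is purely trajectory-borne, a model that sees only
a short static snapshot should do barely better than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_select import ModelDataset, fit_age_scaler
from .errors import ConfigurationError, DataError
from .evaluation import FoldSplit, RocCurve, kfold_split, roc_curve
from .rnn_core import TrainConfig, _sigmoid


@dataclass
class StaticDataset:
    """Per-patient concatenated last-L-visit vectors plus labels."""

    X: np.ndarray  # (n_patients, L * p)
    labels: np.ndarray
    L: int
    feature_names: list[str]
    age_indices: np.ndarray | None = None  # columns holding raw age, per lag

    def __len__(self) -> int:
        return self.X.shape[0]


def build_static_features(
    dataset: ModelDataset,
    L: int = 1,
    exclude_final_visit: bool = False,
    pad: str = "repeat_first",
) -> StaticDataset:
    """Concatenate the features of the last L visits, chronologically.

    If a sequence has fewer than L visits, the earliest visit is repeated on
    the left (``pad='zero'`` pads with zeros instead).  With
    ``exclude_final_visit=True`` the usable window ends one visit earlier —
    the stricter reading of "up to the second to last visit" — provided more
    than one visit exists.
    """
    if L < 1:
        raise ConfigurationError("L must be >= 1")
    if pad not in ("repeat_first", "zero"):
        raise ConfigurationError(f"unknown padding policy {pad!r}")
    p = dataset.n_features
    rows = []
    for s in dataset.sequences:
        F = s.features
        if exclude_final_visit and F.shape[0] > 1:
            F = F[:-1]
        T = F.shape[0]
        if T >= L:
            block = F[T - L:]
        else:
            if pad == "repeat_first":
                padding = np.repeat(F[:1], L - T, axis=0)
            else:
                padding = np.zeros((L - T, p))
            block = np.vstack([padding, F])
        rows.append(block.reshape(-1))
    age_idx = dataset.metadata.get("age_index")
    age_cols = (
        np.array([lag * p + age_idx for lag in range(L)])
        if age_idx is not None
        else None
    )
    names = [f"{name}_lag{L - 1 - lag}" for lag in range(L) for name in dataset.feature_names]
    return StaticDataset(
        X=np.vstack(rows),
        labels=dataset.labels,
        L=L,
        feature_names=names,
        age_indices=age_cols,
    )


def _check_two_classes(labels) -> None:
    if len(np.unique(labels)) < 2:
        raise DataError("both classes are required")


class LogisticScorer:
    """Plain maximum-likelihood logistic regression fitted by gradient ascent.

    No regularization; intercept included; fixed iteration budget.
    """

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef = coef
        self.intercept = intercept

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(np.asarray(X, dtype=float) @ self.coef + self.intercept)


def fit_logistic(
    static: StaticDataset,
    seed: int = 0,
    learning_rate: float = 0.5,
    max_iter: int = 5000,
    X=None,
) -> LogisticScorer:
    """Gradient ascent on the mean log-likelihood, seeded small-random init."""
    X = static.X if X is None else X
    y = static.labels
    _check_two_classes(y)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    w = rng.uniform(-0.01, 0.01, size=d)
    b = 0.0
    for _ in range(max_iter):
        p = _sigmoid(X @ w + b)
        err = y - p  # gradient of the mean log-likelihood
        w += learning_rate * (X.T @ err) / n
        b += learning_rate * err.mean()
    return LogisticScorer(coef=w, intercept=b)


class FfnnScorer:
    """One hidden tanh layer, logistic output: score = sigma(w2 . tanh(W1 x))."""

    def __init__(self, W1: np.ndarray, w2: np.ndarray):
        self.W1 = W1
        self.w2 = w2

    def __call__(self, X: np.ndarray) -> np.ndarray:
        Z = np.tanh(np.asarray(X, dtype=float) @ self.W1.T)
        return _sigmoid(Z @ self.w2)


def fit_ffnn(
    static: StaticDataset,
    n_hidden: int = 20,
    train_config: TrainConfig | None = None,
    seed: int | None = None,
    X=None,
) -> FfnnScorer:
    """Per-example SGD with the same train-AUC early-stopping rule as the RNN.

    This network is coded independently of the recurrent model (its own
    forward and gradients), so it can also serve as a cross-check of the
    recurrent forward pass in the degenerate W_r = 0 case.
    """
    cfg = train_config or TrainConfig()
    if seed is None:
        seed = cfg.seed
    X = static.X if X is None else X
    y = static.labels
    _check_two_classes(y)
    n_ex, d = X.shape
    rng = np.random.default_rng(seed)
    s = cfg.init_scale
    W1 = rng.uniform(-s, s, size=(n_hidden, d))
    w2 = rng.uniform(-s, s, size=n_hidden)
    lr = cfg.learning_rate
    for _ in range(cfg.max_epochs):
        for i in rng.permutation(n_ex):
            x = X[i]
            z = np.tanh(W1 @ x)
            score = float(_sigmoid(w2 @ z))
            delta = score - y[i]
            g_w2 = delta * z
            da = delta * w2 * (1.0 - z**2)
            W1 -= lr * np.outer(da, x)
            w2 -= lr * g_w2
        scores = _sigmoid(np.tanh(X @ W1.T) @ w2)
        if roc_curve(scores, y).auc > cfg.early_stop_train_auc:
            break
    return FfnnScorer(W1=W1, w2=w2)


def _standardize_static_ages(static: StaticDataset, tr_idx, te_idx):
    """Per-fold age scaling for the static design matrix (leakage-free)."""
    Xtr = static.X[tr_idx].copy()
    Xte = static.X[te_idx].copy()
    if static.age_indices is not None:
        ages = Xtr[:, static.age_indices].ravel()
        mean = ages.mean()
        sd = ages.std(ddof=0) or 1.0
        for col in static.age_indices:
            Xtr[:, col] = (Xtr[:, col] - mean) / sd
            Xte[:, col] = (Xte[:, col] - mean) / sd
    return Xtr, Xte


def evaluate_static(
    static: StaticDataset,
    model: str = "logistic",
    k: int = 8,
    seed: int = 0,
    n_hidden: int = 20,
    train_config: TrainConfig | None = None,
    split: FoldSplit | None = None,
) -> tuple[float, RocCurve]:
    """Pooled k-fold AUC of a static model, sharing the fold machinery.

    With the same master seed (and equally ordered data) the folds are
    identical to the recurrent model's, making the comparison paired.
    """
    if model not in ("logistic", "ffnn"):
        raise ConfigurationError(f"unknown static model {model!r}")

    class _Shim:  # duck-typed view for kfold_split
        labels = static.labels

    if split is None:
        split = kfold_split(_Shim(), k=k, seed=seed)
    pooled = np.full(len(static), np.nan)
    for fold in range(split.k):
        tr_idx = split.train_indices(fold)
        te_idx = split.test_indices(fold)
        Xtr, Xte = _standardize_static_ages(static, tr_idx, te_idx)
        sub = StaticDataset(
            X=Xtr, labels=static.labels[tr_idx], L=static.L,
            feature_names=static.feature_names, age_indices=static.age_indices,
        )
        fold_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(fold + 1,)).generate_state(1)[0]
            % (2**31)
        )
        if model == "logistic":
            scorer = fit_logistic(sub, seed=fold_seed)
        else:
            scorer = fit_ffnn(sub, n_hidden=n_hidden, train_config=train_config,
                              seed=fold_seed)
        pooled[te_idx] = scorer(Xte)
    roc = roc_curve(pooled, static.labels)
    return roc.auc, roc
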