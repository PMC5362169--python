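"""Elman recurrent network trained by backpropagation through time.

Model, for one patient j with visit features x_1..x_T (each of length p):

    h_0 = 0
    h_t = tanh(W_r h_{t-1} + W_i x_t)        hidden state, length n
    y_t = logistic(W_o . h_t)                per-visit output in (0, 1)

Only the final output y_T is supervised; it is read as the probability of
developing organ damage within the next two years.  Sequences keep their
native lengths — there is no padding and no truncation of the unrolled
gradient.  Training is plain per-example stochastic gradient descent on the
binary cross-entropy of y_T, with early stopping once the training-set AUC
exceeds a threshold (0.95 by default) to limit over-fitting.

Weight shapes are chosen so the matrix-vector products above are valid:
W_r is (n, n), W_i is (n, p), W_o is a length-n vector.  There are no bias
terms by default (``use_bias`` adds them).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError


@dataclass
class ModelWeights:
    """The three weight arrays of the recurrent model (plus optional biases)."""

    W_r: np.ndarray  # (n, n) hidden -> hidden
    W_i: np.ndarray  # (n, p) input -> hidden
    W_o: np.ndarray  # (n,)   hidden -> output
    b_h: np.ndarray | None = None  # (n,) hidden bias, None when disabled
    b_o: float = 0.0

    @property
    def n_hidden(self) -> int:
        return self.W_r.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W_i.shape[1]

    def copy(self) -> "ModelWeights":
        return ModelWeights(
            self.W_r.copy(), self.W_i.copy(), self.W_o.copy(),
            None if self.b_h is None else self.b_h.copy(), self.b_o,
        )

    def to_json(self, path) -> None:
        payload = {
            "n_hidden": self.n_hidden,
            "n_inputs": self.n_inputs,
            "W_r": self.W_r.tolist(),
            "W_i": self.W_i.tolist(),
            "W_o": self.W_o.tolist(),
            "b_h": None if self.b_h is None else self.b_h.tolist(),
            "b_o": self.b_o,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ModelWeights":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            W_r=np.array(d["W_r"], dtype=float),
            W_i=np.array(d["W_i"], dtype=float),
            W_o=np.array(d["W_o"], dtype=float),
            b_h=None if d.get("b_h") is None else np.array(d["b_h"], dtype=float),
            b_o=float(d.get("b_o", 0.0)),
        )


@dataclass
class TrainConfig:
    n_hidden: int = 100
    learning_rate: float = 0.005
    max_epochs: int = 100
    early_stop_train_auc: float = 0.95
    init_scale: float = 0.1
    spectral_radius: float = 0.95
    use_bias: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_hidden < 1:
            raise ConfigurationError("n_hidden must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.max_epochs < 0:
            raise ConfigurationError("max_epochs must be >= 0")
        if not 0.5 < self.early_stop_train_auc <= 1.0:
            raise ConfigurationError("early_stop_train_auc must be in (0.5, 1]")
        if self.init_scale < 0:
            raise ConfigurationError("init_scale must be >= 0")
        if self.spectral_radius < 0:
            raise ConfigurationError("spectral_radius must be >= 0")


@dataclass
class TrainHistory:
    """Per-epoch mean training loss and training AUC, plus the stop reason."""

    loss: list[float] = field(default_factory=list)
    train_auc: list[float] = field(default_factory=list)
    stop_reason: str = "max_epochs"  # or 'early_stop'

    @property
    def n_epochs(self) -> int:
        return len(self.loss)


def init_weights(p: int, n: int, config: TrainConfig) -> ModelWeights:
    """Seeded uniform init with spectral-radius scaling of the recurrence.

    W_i and W_o are i.i.d. uniform(-init_scale, init_scale).  W_r starts
    uniform and is rescaled so its spectral radius equals
    ``config.spectral_radius``: with a tanh recurrence this is the standard
    way to give the hidden state memory over tens of visits at
    initialization (radius << 1 forgets in a few steps, radius >> 1 blows
    up), which matters here because the clinically relevant signal is
    cumulative over a patient's whole history.  With ``spectral_radius=0``
    or n = 1 and ``init_scale=0`` all entries are zero.  Deterministic given
    (p, n, seed).
    """
    if p < 1 or n < 1:
        raise ConfigurationError(f"dimensions must be positive, got p={p}, n={n}")
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    W_r = rng.uniform(-1.0, 1.0, size=(n, n))
    radius = float(np.max(np.abs(np.linalg.eigvals(W_r))))
    if radius > 0:
        W_r *= config.spectral_radius / radius
    W_i = rng.uniform(-s, s, size=(n, p))
    W_o = rng.uniform(-s, s, size=n)
    b_h = np.zeros(n) if config.use_bias else None
    return ModelWeights(W_r=W_r, W_i=W_i, W_o=W_o, b_h=b_h, b_o=0.0)


def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                    np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))


def forward(weights: ModelWeights, X: np.ndarray):
    """Run the recurrence over a (T, p) feature matrix.

    Returns (H, y, score): hidden trajectory (T, n), per-visit outputs (T,),
    and the final score y_T.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != weights.n_inputs:
        raise DataError(
            f"sequence width {X.shape} incompatible with p={weights.n_inputs}"
        )
    T = X.shape[0]
    n = weights.n_hidden
    H = np.empty((T, n))
    h = np.zeros(n)
    pre = X @ weights.W_i.T  # (T, n) input drive, computed in one BLAS call
    if weights.b_h is not None:
        pre = pre + weights.b_h
    for t in range(T):
        h = np.tanh(weights.W_r @ h + pre[t])
        H[t] = h
    y = _sigmoid(H @ weights.W_o + weights.b_o)
    return H, y, float(y[-1])


def bce_loss(score: float, label: int) -> float:
    """Binary cross-entropy of a single probability against a 0/1 label."""
    if not 0.0 < score < 1.0:
        raise DataError(f"score {score} outside (0, 1)")
    return float(-(label * np.log(score) + (1 - label) * np.log(1.0 - score)))


def _forward_backward(weights: ModelWeights, X: np.ndarray, label: int):
    """One example's loss, final score and exact BPTT gradients."""
    X = np.asarray(X, dtype=float)
    H, y, score = forward(weights, X)
    T, n = H.shape
    # output layer: d(loss)/d(W_o . h_T) = score - label for logistic + BCE
    delta_o = score - label
    g_Wo = delta_o * H[-1]
    g_bo = delta_o
    g_Wr = np.zeros_like(weights.W_r)
    g_Wi = np.zeros_like(weights.W_i)
    g_bh = np.zeros(n) if weights.b_h is not None else None
    dh = delta_o * weights.W_o  # gradient flowing into h_T
    for t in range(T - 1, -1, -1):
        da = dh * (1.0 - H[t] ** 2)  # through tanh
        h_prev = H[t - 1] if t > 0 else np.zeros(n)
        g_Wr += np.outer(da, h_prev)
        g_Wi += np.outer(da, X[t])
        if g_bh is not None:
            g_bh += da
        dh = weights.W_r.T @ da
    loss = bce_loss(min(max(score, 1e-12), 1.0 - 1e-12), label)
    return loss, score, (g_Wr, g_Wi, g_Wo, g_bh, g_bo)


def gradients_bptt(weights: ModelWeights, X: np.ndarray, label: int):
    """Exact gradients of the final-step BCE loss w.r.t. (W_r, W_i, W_o).

    The full sequence is unrolled; nothing is truncated.
    """
    _, _, (g_Wr, g_Wi, g_Wo, _, _) = _forward_backward(weights, X, label)
    return g_Wr, g_Wi, g_Wo


def _train_auc(weights: ModelWeights, seqs, labels) -> float:
    from .evaluation import roc_curve  # local import avoids a cycle

    scores = _scores_fast(weights, seqs)
    return roc_curve(scores, labels).auc


def _scores_fast(weights: ModelWeights, seqs) -> np.ndarray:
    from ._fastpath import HAVE_NUMBA, _score_kernel

    out = np.empty(len(seqs))
    if HAVE_NUMBA and weights.b_h is None:
        for i, X in enumerate(seqs):
            out[i] = _score_kernel(weights.W_r, weights.W_i, weights.W_o, X)
    else:
        for i, X in enumerate(seqs):
            out[i] = forward(weights, X)[2]
    return out


def sgd_train(dataset, config: TrainConfig) -> tuple[ModelWeights, TrainHistory]:
    """Per-example SGD over shuffled epochs with train-AUC early stopping.

    ``dataset`` is a :class:`~sledamage.cohort_select.ModelDataset` or any
    object with ``sequences``; each sequence supplies ``features`` (T, p)
    and ``label``.
    """
    config.validate()
    seqs = [np.asarray(s.features, dtype=float) for s in dataset.sequences]
    labels = np.array([s.label for s in dataset.sequences], dtype=int)
    if len(np.unique(labels)) < 2:
        raise DataError("training requires both classes (AUC is undefined otherwise)")
    p = seqs[0].shape[1]
    weights = init_weights(p, config.n_hidden, config)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    lr = config.learning_rate
    from ._fastpath import HAVE_NUMBA, _sgd_step_kernel

    use_fast = HAVE_NUMBA and weights.b_h is None
    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(seqs))
        losses = np.empty(len(seqs))
        if use_fast:
            for k, i in enumerate(order):
                losses[k] = _sgd_step_kernel(
                    weights.W_r, weights.W_i, weights.W_o,
                    seqs[i], float(labels[i]), lr,
                )
        else:
            for k, i in enumerate(order):
                loss, _, (g_Wr, g_Wi, g_Wo, g_bh, g_bo) = _forward_backward(
                    weights, seqs[i], labels[i]
                )
                losses[k] = loss
                weights.W_r -= lr * g_Wr
                weights.W_i -= lr * g_Wi
                weights.W_o -= lr * g_Wo
                if g_bh is not None:
                    weights.b_h -= lr * g_bh
                    weights.b_o -= lr * g_bo
        auc = _train_auc(weights, seqs, labels)
        history.loss.append(float(losses.mean()))
        history.train_auc.append(auc)
        if auc > config.early_stop_train_auc:
            history.stop_reason = "early_stop"
            break
    return weights, history


def score_sequences(weights: ModelWeights, sequences) -> np.ndarray:
    """Final-visit scores for a list of LabeledSequence (or raw matrices)."""
    seqs = [
        np.ascontiguousarray(s.features if hasattr(s, "features") else s, dtype=float)
        for s in sequences
    ]
    for X in seqs:  # surface shape errors identically on both paths
        if X.ndim != 2 or X.shape[1] != weights.n_inputs:
            raise DataError(
                f"sequence width {X.shape} incompatible with p={weights.n_inputs}"
            )
    return _scores_fast(weights, seqs)
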