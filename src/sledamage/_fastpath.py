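"""Optional numba-compiled kernels for the recurrent model's inner loops.

The per-example forward/backward pass dominates training time; these
kernels implement exactly the same arithmetic as the reference NumPy path
in :mod:`sledamage.rnn_core` without temporary allocations.  Everything
falls back to the NumPy path when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco(a[0]) if a and callable(a[0]) else deco


@njit(cache=False)
def _score_kernel(W_r, W_i, W_o, X):  # pragma: no cover - numba code
    T = X.shape[0]
    n = W_r.shape[0]
    h = np.zeros(n)
    for t in range(T):
        h = np.tanh(np.dot(W_r, h) + np.dot(W_i, X[t]))
    z = np.dot(W_o, h)
    if z >= 0:
        return 1.0 / (1.0 + np.exp(-z))
    ez = np.exp(z)
    return ez / (1.0 + ez)


@njit(cache=False, fastmath=True)
def _sgd_step_kernel(W_r, W_i, W_o, X, label, lr):  # pragma: no cover
    """Forward + full BPTT for one sequence; updates weights in place.

    Returns the pre-update BCE loss of the example.
    """
    T = X.shape[0]
    n = W_r.shape[0]
    p = X.shape[1]
    H = np.empty((T, n))
    h = np.zeros(n)
    for t in range(T):
        h = np.tanh(np.dot(W_r, h) + np.dot(W_i, X[t]))
        H[t] = h
    z = np.dot(W_o, h)
    if z >= 0:
        score = 1.0 / (1.0 + np.exp(-z))
    else:
        ez = np.exp(z)
        score = ez / (1.0 + ez)
    delta = score - label
    g_Wr = np.zeros((n, n))
    g_Wi = np.zeros((n, p))
    dh = delta * W_o
    da = np.empty(n)
    for t in range(T - 1, -1, -1):
        for j in range(n):
            da[j] = dh[j] * (1.0 - H[t, j] * H[t, j])
        if t > 0:
            for j in range(n):
                dj = da[j]
                for kk in range(n):
                    g_Wr[j, kk] += dj * H[t - 1, kk]
        for j in range(n):
            dj = da[j]
            for kk in range(p):
                g_Wi[j, kk] += dj * X[t, kk]
        dh = np.dot(da, W_r)
    for j in range(n):
        W_o[j] -= lr * delta * H[T - 1, j]
        for kk in range(n):
            W_r[j, kk] -= lr * g_Wr[j, kk]
        for kk in range(p):
            W_i[j, kk] -= lr * g_Wi[j, kk]
    eps = 1e-12
    s = min(max(score, eps), 1.0 - eps)
    if label == 1.0:
        return -np.log(s)
    return -np.log(1.0 - s)
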