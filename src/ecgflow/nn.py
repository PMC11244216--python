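"""A small 1-D convolutional binary classifier for short tabular feature vectors.

Architecture: valid 1-D convolution (kernel 3, 16 filters) over the feature
vector, ReLU, flatten, dense layer to a single logit, sigmoid. Trained with
full-batch Adam on binary cross-entropy. Deliberately tiny — it fits a
9-feature cardiac-risk vector in well under a second on one CPU core — and
fully deterministic given its seed.

Implements the scikit-learn estimator triad (fit / predict /
predict_proba) so it can be swapped into model-comparison loops alongside
library classifiers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Conv1DClassifier:
    """Conv(kernel 3, ``n_filters``) -> ReLU -> dense -> sigmoid."""

    def __init__(
        self,
        n_filters: int = 16,
        kernel_size: int = 3,
        epochs: int = 300,
        lr: float = 0.01,
        seed: int = 0,
    ) -> None:
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.epochs = epochs
        self.lr = lr
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Conv1DClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, d = X.shape
        if d < self.kernel_size:
            raise ValueError(f"need >= {self.kernel_size} features, got {d}")
        rng = np.random.default_rng(self.seed)
        k, f = self.kernel_size, self.n_filters
        p = d - k + 1  # conv output positions
        # He-style init for the ReLU conv, Glorot-style for the dense head
        Wc = rng.normal(0.0, np.sqrt(2.0 / k), size=(f, k))
        bc = np.zeros(f)
        Wd = rng.normal(0.0, np.sqrt(1.0 / (p * f)), size=p * f)
        bd = 0.0

        params = [Wc, bc, Wd, np.array([bd])]
        m = [np.zeros_like(q) for q in params]
        v = [np.zeros_like(q) for q in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        windows = sliding_window_view(X, k, axis=1)  # (n, p, k)
        for step in range(1, self.epochs + 1):
            Wc, bc, Wd, bd_arr = params
            conv = windows @ Wc.T + bc          # (n, p, f)
            act = np.maximum(conv, 0.0)
            flat = act.reshape(n, -1)
            logit = flat @ Wd + bd_arr[0]
            prob = _sigmoid(logit)

            dlogit = (prob - y) / n
            gWd = flat.T @ dlogit
            gbd = np.array([dlogit.sum()])
            dflat = np.outer(dlogit, Wd)
            dconv = dflat.reshape(n, p, f) * (conv > 0)
            gWc = np.einsum("npf,npk->fk", dconv, windows)
            gbc = dconv.sum(axis=(0, 1))

            for q, g, mi, vi in zip(params, [gWc, gbc, gWd, gbd], m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                mhat = mi / (1 - beta1**step)
                vhat = vi / (1 - beta2**step)
                q -= self.lr * mhat / (np.sqrt(vhat) + eps)

        self._params = params
        self._input_dim = d
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._input_dim:
            raise ValueError("feature count differs from the fitted model")
        Wc, bc, Wd, bd_arr = self._params
        windows = sliding_window_view(X, self.kernel_size, axis=1)
        act = np.maximum(windows @ Wc.T + bc, 0.0)
        p1 = _sigmoid(act.reshape(len(X), -1) @ Wd + bd_arr[0])
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # minimal estimator-protocol support
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_filters": self.n_filters,
            "kernel_size": self.kernel_size,
            "epochs": self.epochs,
            "lr": self.lr,
            "seed": self.seed,
        }

    def set_params(self, **kwargs) -> "Conv1DClassifier":
        for key, value in kwargs.items():
            setattr(self, key, value)
        return self
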