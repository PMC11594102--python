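"""Two-layer stacked LSTM binary classifier in numpy.

Architecture: two stacked LSTM layers with 64 hidden units each; a
fully connected head maps the final hidden state of the second layer to
a scalar logit.  Trained with Adam on binary cross-entropy, fixed
epochs and batch size, fully seeded.

Inputs are 3-D arrays ``(n, T, d)``.  In the default *tabular* mode the
engineered feature vector is fed as a length-1 sequence (T = 1); in
*sequence* mode per-position one-hot residues are truncated/padded to a
fixed length.  Implemented with explicit backpropagation through time;
intended for the moderate problem sizes this package trains at.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .sequence_io import AMINO_ACIDS


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class _LSTMLayer:
    """One LSTM layer; gate order (i, f, g, o) packed in a single matrix."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(d_in + d_hidden)
        self.W = rng.uniform(-scale, scale, size=(d_in + d_hidden, 4 * d_hidden))
        self.b = np.zeros(4 * d_hidden)
        self.b[d_hidden : 2 * d_hidden] = 1.0  # forget-gate bias
        self.h = d_hidden

    def params(self):
        return [self.W, self.b]

    def forward(self, X: np.ndarray):
        """X: (n, T, d_in) -> outputs (n, T, h) plus caches for backprop."""
        n, T, _ = X.shape
        h = self.h
        hs = np.zeros((n, T + 1, h))
        cs = np.zeros((n, T + 1, h))
        caches = []
        for t in range(T):
            z = np.concatenate([X[:, t, :], hs[:, t, :]], axis=1)
            gates = z @ self.W + self.b
            i = _sigmoid(gates[:, :h])
            f = _sigmoid(gates[:, h : 2 * h])
            g = np.tanh(gates[:, 2 * h : 3 * h])
            o = _sigmoid(gates[:, 3 * h :])
            c = f * cs[:, t, :] + i * g
            tc = np.tanh(c)
            hs[:, t + 1, :] = o * tc
            cs[:, t + 1, :] = c
            caches.append((z, i, f, g, o, tc))
        return hs, cs, caches

    def backward(self, X, hs, cs, caches, dH):
        """dH: (n, T, h) gradient on outputs; returns (dX, dW, db)."""
        n, T, d_in = X.shape
        h = self.h
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for t in range(T - 1, -1, -1):
            z, i, f, g, o, tc = caches[t]
            dh = dH[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * cs[:, t, :]
            dgates = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dW += z.T @ dgates
            db += dgates.sum(axis=0)
            dz = dgates @ self.W.T
            dX[:, t, :] = dz[:, :d_in]
            dh_next = dz[:, d_in:]
            dc_next = dc * f
        return dX, dW, db


class LSTMClassifier(BaseEstimator, ClassifierMixin):
    """Stacked 2-layer LSTM (64 + 64 hidden units) with a scalar head."""

    def __init__(
        self,
        hidden: int = 64,
        epochs: int = 30,
        batch_size: int = 32,
        lr: float = 1e-3,
        mode: str = "tabular",
        max_len: int = 500,
        seed: int = 0,
    ):
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.mode = mode
        self.max_len = max_len
        self.seed = seed

    # -- input shaping ------------------------------------------------------
    def _to_tensor(self, X) -> np.ndarray:
        if self.mode == "tabular":
            X = np.asarray(X, dtype=float)
            if X.ndim == 2:
                X = X[:, None, :]  # length-1 sequence
            return X
        if self.mode == "sequence":
            idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
            out = np.zeros((len(X), self.max_len, 20))
            for r, seq in enumerate(X):
                for t, a in enumerate(seq[: self.max_len]):
                    out[r, t, idx[a]] = 1.0
            return out
        raise ValueError("mode must be 'tabular' or 'sequence'")

    # -- training -----------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        T = self._to_tensor(X)
        n, _, d_in = T.shape
        rng = np.random.default_rng(self.seed)
        self.layer1_ = _LSTMLayer(d_in, self.hidden, rng)
        self.layer2_ = _LSTMLayer(self.hidden, self.hidden, rng)
        self.w_head_ = rng.uniform(-0.1, 0.1, size=self.hidden)
        self.b_head_ = 0.0
        params = self.layer1_.params() + self.layer2_.params() + [self.w_head_]
        m = [np.zeros_like(p) for p in params] + [0.0]
        v = [np.zeros_like(p) for p in params] + [0.0]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                Xb, yb = T[batch], y[batch]
                hs1, cs1, ca1 = self.layer1_.forward(Xb)
                H1 = hs1[:, 1:, :]
                hs2, cs2, ca2 = self.layer2_.forward(H1)
                h_last = hs2[:, -1, :]
                logit = h_last @ self.w_head_ + self.b_head_
                p = _sigmoid(logit)
                # BCE gradient
                dlogit = (p - yb) / len(batch)
                dw_head = h_last.T @ dlogit
                db_head = dlogit.sum()
                dH2 = np.zeros_like(hs2[:, 1:, :])
                dH2[:, -1, :] = dlogit[:, None] * self.w_head_
                dH1, dW2, db2 = self.layer2_.backward(H1, hs2, cs2, ca2, dH2)
                _, dW1, db1 = self.layer1_.backward(Xb, hs1, cs1, ca1, dH1)
                grads = [dW1, db1, dW2, db2, dw_head, db_head]
                tgt = params + ["bhead"]
                step += 1
                for k, g in enumerate(grads):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * (g * g if k < 5 else g**2)
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    upd = self.lr * mhat / (np.sqrt(vhat) + eps)
                    if k < 5:
                        tgt[k] -= upd
                    else:
                        self.b_head_ -= upd
        self.classes_ = np.array([0, 1])
        return self

    # -- inference ----------------------------------------------------------
    def _scores(self, X) -> np.ndarray:
        T = self._to_tensor(X)
        hs1, _, _ = self.layer1_.forward(T)
        hs2, _, _ = self.layer2_.forward(hs1[:, 1:, :])
        return _sigmoid(hs2[:, -1, :] @ self.w_head_ + self.b_head_)

    def predict_proba(self, X) -> np.ndarray:
        p = self._scores(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self._scores(X) >= 0.5).astype(int)
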