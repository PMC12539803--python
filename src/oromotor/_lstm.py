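"""Minimal LSTM sequence regressor (numpy, Adam, truncated BPTT).

A single-layer LSTM with a linear readout trained on mean squared error.
Written for small neural-decoding problems (tens of input channels, a few
thousand time steps); intentionally free of deep-learning framework
dependencies. The interface follows scikit-learn: ``fit(X, y)`` /
``predict(X)`` on a time-ordered feature matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["LSTMRegressor"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMRegressor(BaseEstimator, RegressorMixin):
    """LSTM with linear readout for sequence regression.

    Parameters
    ----------
    n_hidden : LSTM state size.
    epochs : full passes over the training subsequences.
    lr : Adam learning rate.
    seq_len : training subsequence length (truncated BPTT horizon).
    clip : global gradient-norm clip.
    seed : weight-initialisation and shuffling seed.
    """

    def __init__(self, n_hidden: int = 32, epochs: int = 20, lr: float = 0.01,
                 seq_len: int = 20, batch_size: int = 4, clip: float = 5.0,
                 seed: int = 0):
        self.n_hidden = n_hidden
        self.epochs = epochs
        self.lr = lr
        self.seq_len = seq_len
        self.batch_size = batch_size
        self.clip = clip
        self.seed = seed

    # -- parameter handling -------------------------------------------------
    def _init_params(self, d: int, rng: np.random.Generator) -> dict:
        h = self.n_hidden
        s = 1.0 / np.sqrt(h)
        p = {
            "Wx": rng.uniform(-s, s, size=(d, 4 * h)),
            "Wh": rng.uniform(-s, s, size=(h, 4 * h)),
            "b": np.zeros(4 * h),
            "Wy": rng.uniform(-s, s, size=(h, 1)),
            "by": np.zeros(1),
        }
        p["b"][h:2 * h] = 1.0  # forget-gate bias: remember by default
        return p

    def _forward(self, X: np.ndarray, p: dict, h0=None, c0=None, cache: bool = False):
        """X is (B, L, D). Returns predictions (B, L) and optional cache."""
        B, L, D = X.shape
        H = self.n_hidden
        h = np.zeros((B, H)) if h0 is None else h0
        c = np.zeros((B, H)) if c0 is None else c0
        ys = np.empty((B, L))
        steps = []
        for t in range(L):
            a = X[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            ys[:, t] = (h_new @ p["Wy"] + p["by"])[:, 0]
            if cache:
                steps.append((X[:, t], h, c, i, f, g, o, c_new, tc, h_new))
            h, c = h_new, c_new
        return ys, steps, h, c

    def _backward(self, dy: np.ndarray, steps: list, p: dict) -> dict:
        H = self.n_hidden
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dh_next = np.zeros_like(steps[0][1])
        dc_next = np.zeros_like(steps[0][2])
        for t in range(len(steps) - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, c_new, tc, h_new = steps[t]
            dyt = dy[:, t:t + 1]
            grads["Wy"] += h_new.T @ dyt
            grads["by"] += dyt.sum(axis=0)
            dh = dyt @ p["Wy"].T + dh_next
            do = dh * tc
            dtc = dh * o * (1.0 - tc ** 2) + dc_next
            df = dtc * c_prev
            di = dtc * g
            dg = dtc * i
            dc_next = dtc * f
            da = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o),
            ], axis=1)
            grads["Wx"] += x.T @ da
            grads["Wh"] += h_prev.T @ da
            grads["b"] += da.sum(axis=0)
            dh_next = da @ p["Wh"].T
        return grads

    # -- public API ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMRegressor":
        """Train on a time-ordered sequence ``X`` (T, D), targets ``y`` (T,).

        The sequence is cut into non-overlapping subsequences of
        ``seq_len`` steps; each epoch shuffles the subsequences and runs one
        Adam update per mini-batch of ``batch_size`` of them.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or y.size != X.shape[0]:
            raise ValueError("X must be (T, D) with one target per step")
        T, D = X.shape
        L = min(self.seq_len, T)
        n_seq = T // L
        Xs = X[:n_seq * L].reshape(n_seq, L, D)
        ys = y[:n_seq * L].reshape(n_seq, L)
        rng = np.random.default_rng(self.seed)
        p = self._init_params(D, rng)
        mom = {k: np.zeros_like(v) for k, v in p.items()}
        vel = {k: np.zeros_like(v) for k, v in p.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        for _ in range(self.epochs):
            order = rng.permutation(n_seq)
            for lo in range(0, n_seq, self.batch_size):
                batch = order[lo:lo + self.batch_size]
                pred, steps, _, _ = self._forward(Xs[batch], p, cache=True)
                dy = 2.0 * (pred - ys[batch]) / pred.size
                grads = self._backward(dy, steps, p)
                gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
                if gnorm > self.clip:
                    for k in grads:
                        grads[k] *= self.clip / gnorm
                step += 1
                for k in p:
                    mom[k] = b1 * mom[k] + (1 - b1) * grads[k]
                    vel[k] = b2 * vel[k] + (1 - b2) * grads[k] ** 2
                    mhat = mom[k] / (1 - b1 ** step)
                    vhat = vel[k] / (1 - b2 ** step)
                    p[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
        self.params_ = p
        self.n_features_in_ = D
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Stepwise prediction over a time-ordered sequence (T, D)."""
        X = np.asarray(X, dtype=float)
        pred, _, _, _ = self._forward(X[None, :, :], self.params_)
        return pred[0]
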