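"""Minimal seeded LSTM regressor in numpy (forward, BPTT, Adam, MAE loss).

Single recurrent layer with tanh cell activation and a linear head on the
final hidden state; sized for short scalar sequences (the 100-sample
deviation-forecasting task), where a hand-rolled float32 implementation
trains in seconds to minutes on one CPU.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTMNet:
    """One-layer LSTM, input dim 1, scalar output.

    Weights are stored as a single ``(1 + H, 4H)`` matrix over the
    concatenated ``[x_t, h_{t-1}]`` with gate order (i, f, g, o); the forget
    gate bias is initialised at 1.
    """

    def __init__(self, hidden: int, seed: int, input_dim: int = 1):
        rng = np.random.default_rng(seed)
        H, D = hidden, input_dim
        k = 1.0 / np.sqrt(H)
        self.H, self.D = H, D
        self.W = rng.uniform(-k, k, size=(D + H, 4 * H)).astype(np.float32)
        self.b = np.zeros(4 * H, dtype=np.float32)
        self.b[H:2 * H] = 1.0
        self.w_out = rng.uniform(-k, k, size=H).astype(np.float32)
        self.b_out = np.float32(0.0)
        self._adam = None

    # ----- forward / backward -------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        """X: (B, T) float32 (input_dim 1). Returns predictions (B,)."""
        B, T = X.shape
        H = self.H
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        caches = [] if cache else None
        for t in range(T):
            a = np.concatenate([X[:, t:t + 1], h], axis=1)
            z = a @ self.W + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            if cache:
                caches.append((a, i, f, g, o, c_prev, tc))
        y = h @ self.w_out + self.b_out
        if cache:
            return y, (caches, h)
        return y

    def backward(self, X, y_true, y_pred, fwd_cache):
        """Gradients of mean-absolute-error w.r.t. all parameters."""
        caches, h_T = fwd_cache
        B, T = X.shape
        H = self.H
        dy = np.sign(y_pred - y_true).astype(np.float32) / np.float32(B)
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dw_out = h_T.T @ dy
        db_out = dy.sum()
        dh = np.outer(dy, self.w_out).astype(np.float32)
        dc = np.zeros((B, H), dtype=np.float32)
        Wh = self.W[self.D:]          # (H, 4H)
        for t in range(T - 1, -1, -1):
            a, i, f, g, o, c_prev, tc = caches[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dW += a.T @ dz
            db += dz.sum(axis=0)
            dh = dz @ Wh.T
            dc = dc * f
        return dW, db, dw_out.astype(np.float32), np.float32(db_out)

    # ----- optimisation --------------------------------------------------
    def adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8,
                  clip_norm=5.0):
        params = [self.W, self.b, self.w_out]
        gW, gb, gw, gb_out = grads
        glist = [gW, gb, gw]
        norm = np.sqrt(sum(float((g * g).sum()) for g in glist) + gb_out ** 2)
        scale = np.float32(min(1.0, clip_norm / (norm + 1e-12)))
        if self._adam is None:
            self._adam = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params] + [np.float32(0.0)],
                "v": [np.zeros_like(p) for p in params] + [np.float32(0.0)],
            }
        st = self._adam
        st["t"] += 1
        t = st["t"]
        allg = glist + [gb_out]
        for idx, g in enumerate(allg):
            g = g * scale
            st["m"][idx] = beta1 * st["m"][idx] + (1 - beta1) * g
            st["v"][idx] = beta2 * st["v"][idx] + (1 - beta2) * (g * g)
            mhat = st["m"][idx] / (1 - beta1 ** t)
            vhat = st["v"][idx] / (1 - beta2 ** t)
            upd = (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)
            if idx < 3:
                params[idx] -= upd
            else:
                self.b_out -= upd

    def get_weights(self):
        return (self.W.copy(), self.b.copy(), self.w_out.copy(),
                np.float32(self.b_out))

    def set_weights(self, weights):
        self.W, self.b, self.w_out, self.b_out = (
            weights[0].copy(), weights[1].copy(), weights[2].copy(),
            np.float32(weights[3]))


def train_mae(net: LSTMNet, X_train, y_train, X_val, y_val, *,
              max_epochs: int, patience: int, lr: float, batch_size: int,
              seed: int):
    """Minibatch Adam training on MAE with early stopping on validation MAE.

    Returns (best validation MAE, epoch history). The network is left at the
    best-validation weights.
    """
    rng = np.random.default_rng(seed)
    n = X_train.shape[0]
    best_val = np.inf
    best_w = net.get_weights()
    history = []
    wait = 0
    for _epoch in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X_train[idx], y_train[idx]
            pred, cache = net.forward(xb, cache=True)
            grads = net.backward(xb, yb, pred, cache)
            net.adam_step(grads, lr)
        val_pred = net.forward(X_val)
        val_mae = float(np.abs(val_pred - y_val).mean())
        history.append(val_mae)
        if val_mae < best_val - 1e-6:
            best_val = val_mae
            best_w = net.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    net.set_weights(best_w)
    return best_val, history
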