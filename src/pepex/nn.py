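"""Minimal numpy neural-network kernels: GRU forward/backward and Adam.

Everything is float64 and time-major.  Gate layout inside the fused weight
matrices is [reset | update | candidate], i.e. for input x_t and hidden h:

    r = sigmoid(x W_xr + h W_hr + b_xr + b_hr)
    u = sigmoid(x W_xu + h W_hu + b_xu + b_hu)
    c = tanh(x W_xc + b_xc + r * (h W_hc + b_hc))
    h' = (1 - u) * c + u * h

The backward pass is exact BPTT over these equations; a central-difference
gradient check in the test suite pins it down.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gru_forward(X: np.ndarray, h0: np.ndarray, Wx, Wh, bx, bh):
    """Run a GRU over time-major inputs.

    X: (T, B, M); h0: (B, H); Wx: (M, 3H); Wh: (H, 3H); bx, bh: (3H,).
    Returns Hs of shape (T+1, B, H) (Hs[0] == h0) and the backward cache.
    """
    T, B, _ = X.shape
    H = Wh.shape[0]
    Hs = np.empty((T + 1, B, H))
    Hs[0] = h0
    R = np.empty((T, B, H))
    U = np.empty((T, B, H))
    C = np.empty((T, B, H))
    HHc = np.empty((T, B, H))
    for t in range(T):
        gx = X[t] @ Wx + bx
        gh = Hs[t] @ Wh + bh
        r = sigmoid(gx[:, :H] + gh[:, :H])
        u = sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
        hh = gh[:, 2 * H :]
        c = np.tanh(gx[:, 2 * H :] + r * hh)
        Hs[t + 1] = (1.0 - u) * c + u * Hs[t]
        R[t], U[t], C[t], HHc[t] = r, u, c, hh
    return Hs, (X, R, U, C, HHc)


def gru_backward(dH_inject: np.ndarray, Hs: np.ndarray, cache, Wx, Wh):
    """BPTT given per-step output gradients dH_inject[t] wrt h_{t+1}.

    Returns (dX, dh0, dWx, dWh, dbx, dbh).
    """
    X, R, U, C, HHc = cache
    T, B, M = X.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    dbx = np.zeros(3 * H)
    dbh = np.zeros(3 * H)
    dX = np.empty_like(X)
    dh = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dh = dh + dH_inject[t]
        r, u, c, hh = R[t], U[t], C[t], HHc[t]
        h_prev = Hs[t]
        dpre_u = dh * (h_prev - c) * u * (1.0 - u)
        dc = dh * (1.0 - u)
        dpre_c = dc * (1.0 - c * c)
        dhh = dpre_c * r
        dpre_r = dpre_c * hh * r * (1.0 - r)
        dgx = np.concatenate([dpre_r, dpre_u, dpre_c], axis=1)
        dgh = np.concatenate([dpre_r, dpre_u, dhh], axis=1)
        dX[t] = dgx @ Wx.T
        dWx += X[t].T @ dgx
        dbx += dgx.sum(axis=0)
        dWh += h_prev.T @ dgh
        dbh += dgh.sum(axis=0)
        dh = dh * u + dgh @ Wh.T
    return dX, dh, dWx, dWh, dbx, dbh


def log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))


class Adam:
    """Plain Adam over a dict of parameter arrays (updated in place)."""

    def __init__(self, params: dict, lr: float = 3e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
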