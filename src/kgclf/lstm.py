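"""Minimal NumPy LSTM layer with exact backpropagation through time.

Used as the recurrent encoder of the sequence tagger; gradients are verified
against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTMCell:
    """Single-layer LSTM over one sequence at a time.

    Weight layout: W has shape (4H, D + H), gate order (input, forget,
    cell-candidate, output); b has shape (4H,).
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        scale = 1.0 / np.sqrt(input_dim + hidden_dim)
        self.W = rng.uniform(-scale, scale, size=(4 * hidden_dim, input_dim + hidden_dim))
        self.b = np.zeros(4 * hidden_dim)
        # forget-gate bias init at 1 for stable early training
        self.b[hidden_dim:2 * hidden_dim] = 1.0

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray):
        """x: (n, D) -> h_seq: (n, H) plus a cache for backward."""
        n = x.shape[0]
        H = self.hidden_dim
        h = np.zeros(H)
        c = np.zeros(H)
        hs = np.empty((n, H))
        cache = []
        for t in range(n):
            xc = np.concatenate([x[t], h])
            z = self.W @ xc + self.b
            i = _sigmoid(z[:H])
            f = _sigmoid(z[H:2 * H])
            g = np.tanh(z[2 * H:3 * H])
            o = _sigmoid(z[3 * H:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[t] = h
            cache.append((xc, i, f, g, o, c, tc))
        return hs, cache

    def backward(self, dh_seq: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (dx_seq, dW, db) for upstream gradients dh_seq (n, H)."""
        n = dh_seq.shape[0]
        H = self.hidden_dim
        D = self.input_dim
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dx = np.empty((n, D))
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(n - 1, -1, -1):
            xc, i, f, g, o, c, tc = cache[t]
            c_prev = cache[t - 1][5] if t > 0 else np.zeros(H)
            dh = dh_seq[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ])
            dW += np.outer(dz, xc)
            db += dz
            dxc = self.W.T @ dz
            dx[t] = dxc[:D]
            dh_next = dxc[D:]
            dc_next = dc * f
        return dx, dW, db


class BiLSTM:
    """Forward + backward LSTM with concatenated hidden states (n, 2H)."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.fwd = LSTMCell(input_dim, hidden_dim, rng)
        self.bwd = LSTMCell(input_dim, hidden_dim, rng)
        self.output_dim = 2 * hidden_dim

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"fwd.W": self.fwd.W, "fwd.b": self.fwd.b,
                "bwd.W": self.bwd.W, "bwd.b": self.bwd.b}

    def forward(self, x: np.ndarray):
        hf, cf = self.fwd.forward(x)
        hb, cb = self.bwd.forward(x[::-1])
        return np.concatenate([hf, hb[::-1]], axis=1), (cf, cb)

    def backward(self, dh_seq: np.ndarray, cache):
        H = self.fwd.hidden_dim
        cf, cb = cache
        dxf, dWf, dbf = self.fwd.backward(dh_seq[:, :H], cf)
        dxb, dWb, dbb = self.bwd.backward(dh_seq[::-1, H:], cb)
        grads = {"fwd.W": dWf, "fwd.b": dbf, "bwd.W": dWb, "bwd.b": dbb}
        return dxf + dxb[::-1], grads


class Adam:
    """Adam optimizer over a dict of parameter arrays (updated in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        """Apply one minimizing update from a gradient dict."""
        self.t += 1
        for key, g in grads.items():
            p = self.params[key]
            if self.weight_decay:
                p *= 1.0 - self.lr * self.weight_decay  # decoupled decay
            m = self.m[key]
            v = self.v[key]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
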