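"""Bidirectional recurrent sequence classifier in plain numpy.

One LSTM per direction; the backward direction runs over per-sequence
reversed inputs. The two final hidden states are concatenated and fed to a
one-hidden-layer fully-connected head with a sigmoid output. Training is
mini-batch Adam on binary cross-entropy, with optional per-class weights.

Everything is float64 and deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from clinneg.errors import ConfigurationError

__all__ = ["HyperParams", "BiLSTMNetwork"]


@dataclass
class HyperParams:
    """Training and architecture settings; all overridable."""

    emb_dim: int = 300
    hidden: int = 128
    fc_hidden: int = 64
    epochs: int = 12
    batch_size: int = 32
    lr: float = 1e-3
    max_len: int = 80
    class_weighting: bool = False

    def validate(self) -> None:
        for name in ("emb_dim", "hidden", "fc_hidden", "epochs", "batch_size", "max_len"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"hyperparameter {name} must be >= 1")
        if self.lr <= 0:
            raise ConfigurationError("lr must be positive")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTM:
    """Single-direction LSTM over right-padded batches. Gate order i,f,g,o."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-s, s, (input_dim, 4 * hidden))
        self.Wh = rng.uniform(-s, s, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.h = hidden

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray, mask: np.ndarray):
        """X: (B, T, d); mask: (B, T) in {0,1}. Returns final h and a cache."""
        B, T, _ = X.shape
        H = self.h
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            m = mask[:, t : t + 1]
            z = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h.copy(), c.copy(), i, f, g, o, tc, m))
            c = m * c_new + (1 - m) * c
            h = m * h_new + (1 - m) * h
        return h, (X, cache)

    def backward(self, dh_final: np.ndarray, ctx):
        """Backprop the final-state gradient through time.

        Returns (dX, grads) with grads matching :meth:`params` order.
        """
        X, cache = ctx
        B, T, d = X.shape
        H = self.h
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        dh_next = dh_final
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc, m = cache[t]
            dh = dh_next * m
            dc = dc_next * m + dh * o * (1 - tc * tc)
            do = dh * tc
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            dWx += X[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T + dh_next * (1 - m)
            dc_next = dc * f + dc_next * (1 - m)
        return dX, [dWx, dWh, db]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class BiLSTMNetwork:
    """Embedding table + two LSTMs + fully-connected head."""

    def __init__(self, vocab_size: int, hp: HyperParams, rng: np.random.Generator,
                 embedding_init: np.ndarray | None = None):
        hp.validate()
        self.hp = hp
        d, H = hp.emb_dim, hp.hidden
        self.E = (rng.random((vocab_size, d)) - 0.5) * 0.2
        if embedding_init is not None:
            if embedding_init.shape != (vocab_size, d):
                raise ConfigurationError(
                    f"embedding_init shape {embedding_init.shape} != ({vocab_size}, {d})"
                )
            self.E = embedding_init.astype(float).copy()
        self.fwd = _LSTM(d, H, rng)
        self.bwd = _LSTM(d, H, rng)
        s = 1.0 / np.sqrt(2 * H)
        self.W1 = rng.uniform(-s, s, (2 * H, hp.fc_hidden))
        self.b1 = np.zeros(hp.fc_hidden)
        self.W2 = rng.uniform(-s, s, (hp.fc_hidden, 1))
        self.b2 = np.zeros(1)

    # -- helpers ------------------------------------------------------------

    def _all_params(self):
        return (
            [self.E]
            + self.fwd.params()
            + self.bwd.params()
            + [self.W1, self.b1, self.W2, self.b2]
        )

    @staticmethod
    def _reverse_ids(ids: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        rev = np.zeros_like(ids)
        for r, (row, n) in enumerate(zip(ids, lengths)):
            rev[r, :n] = row[:n][::-1]
        return rev

    def _forward(self, ids: np.ndarray, lengths: np.ndarray):
        mask = (np.arange(ids.shape[1])[None, :] < lengths[:, None]).astype(float)
        rev = self._reverse_ids(ids, lengths)
        Xf = self.E[ids]
        Xb = self.E[rev]
        hf, ctx_f = self.fwd.forward(Xf, mask)
        hb, ctx_b = self.bwd.forward(Xb, mask)
        z = np.concatenate([hf, hb], axis=1)
        a_pre = z @ self.W1 + self.b1
        a = np.maximum(a_pre, 0.0)
        p = _sigmoid(a @ self.W2 + self.b2)[:, 0]
        cache = (ids, rev, mask, ctx_f, ctx_b, z, a_pre, a, p)
        return p, cache

    def predict_proba(self, ids: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """Probabilities in [0, 1] for a padded id batch."""
        p, _ = self._forward(ids, lengths)
        return p

    # -- training -----------------------------------------------------------

    def _backward(self, cache, y: np.ndarray, weights: np.ndarray):
        ids, rev, mask, ctx_f, ctx_b, z, a_pre, a, p = cache
        B = len(y)
        # d(weighted BCE)/d(logit) = w * (p - y) / B
        dlogit = (weights * (p - y) / B)[:, None]
        dW2 = a.T @ dlogit
        db2 = dlogit.sum(axis=0)
        da = dlogit @ self.W2.T
        da[a_pre <= 0] = 0.0
        dW1 = z.T @ da
        db1 = da.sum(axis=0)
        dz = da @ self.W1.T
        H = self.hp.hidden
        dXf, grads_f = self.fwd.backward(dz[:, :H], ctx_f)
        dXb, grads_b = self.bwd.backward(dz[:, H:], ctx_b)
        dE = np.zeros_like(self.E)
        np.add.at(dE, ids.ravel(), dXf.reshape(-1, dXf.shape[-1]))
        np.add.at(dE, rev.ravel(), dXb.reshape(-1, dXb.shape[-1]))
        return [dE] + grads_f + grads_b + [dW1, db1, dW2, db2]

    def fit(
        self,
        ids: np.ndarray,
        lengths: np.ndarray,
        labels: np.ndarray,
        seed: int = 0,
    ) -> list[float]:
        """Train in place; returns per-epoch mean losses."""
        hp = self.hp
        rng = np.random.default_rng(seed)
        y = labels.astype(float)
        if hp.class_weighting:
            pos = max(y.sum(), 1.0)
            neg = max(len(y) - y.sum(), 1.0)
            w_pos, w_neg = len(y) / (2 * pos), len(y) / (2 * neg)
        else:
            w_pos = w_neg = 1.0
        weights_all = np.where(y == 1.0, w_pos, w_neg)

        opt = _Adam(self._all_params(), hp.lr)
        losses = []
        n = len(y)
        for _epoch in range(hp.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, hp.batch_size):
                idx = order[start : start + hp.batch_size]
                p, cache = self._forward(ids[idx], lengths[idx])
                w = weights_all[idx]
                eps = 1e-12
                loss = -np.mean(
                    w * (y[idx] * np.log(p + eps) + (1 - y[idx]) * np.log(1 - p + eps))
                )
                total += loss * len(idx)
                grads = self._backward(cache, y[idx], w)
                opt.step(grads)
            losses.append(total / n)
        return losses

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            "E": self.E,
            "fwd_Wx": self.fwd.Wx, "fwd_Wh": self.fwd.Wh, "fwd_b": self.fwd.b,
            "bwd_Wx": self.bwd.Wx, "bwd_Wh": self.bwd.Wh, "bwd_b": self.bwd.b,
            "W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2,
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.E = state["E"]
        self.fwd.Wx, self.fwd.Wh, self.fwd.b = state["fwd_Wx"], state["fwd_Wh"], state["fwd_b"]
        self.bwd.Wx, self.bwd.Wh, self.bwd.b = state["bwd_Wx"], state["bwd_Wh"], state["bwd_b"]
        self.W1, self.b1 = state["W1"], state["b1"]
        self.W2, self.b2 = state["W2"], state["b2"]
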