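"""Minimal bidirectional LSTM sequence classifier in pure numpy.

Architecture: one bidirectional LSTM layer; the forward and backward
hidden states are mean-pooled over time, concatenated, and projected by a
single fully connected layer to class logits with a softmax cross-entropy
loss.  Trained full-batch with Adam and global gradient-norm clipping.
Everything is seeded, so training is bit-deterministic for a fixed
(data, config, seed).

The implementation is intentionally small (a few hundred lines, no
autograd): sequences here are short ROI-displacement traces and the
training sets are tens to hundreds of samples, where full-batch numpy is
fast and exactly reproducible.  Gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class BiLSTMConfig:
    n_channels: int
    n_classes: int = 3
    hidden: int = 24
    epochs: int = 80
    learning_rate: float = 0.02
    clip_norm: float = 5.0
    seed: int = 0


class _LSTMDirection:
    """Parameters and forward/backward pass for one direction."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(hidden)
        self.wx = rng.uniform(-s, s, size=(c_in, 4 * hidden))
        self.wh = rng.uniform(-s, s, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.hidden = hidden

    def params(self) -> list[np.ndarray]:
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray):
        """x: (B, T, C) -> h: (B, T, H) plus caches for backprop."""
        b_n, t_n, _ = x.shape
        hd = self.hidden
        h = np.zeros((b_n, t_n, hd))
        cache = []
        h_t = np.zeros((b_n, hd))
        c_t = np.zeros((b_n, hd))
        for t in range(t_n):
            z = x[:, t] @ self.wx + h_t @ self.wh + self.b
            i = _sigmoid(z[:, :hd])
            f = _sigmoid(z[:, hd : 2 * hd])
            g = np.tanh(z[:, 2 * hd : 3 * hd])
            o = _sigmoid(z[:, 3 * hd :])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tc
            h[:, t] = h_t
            cache.append((i, f, g, o, c_prev, tc, h_prev))
        return h, cache

    def backward(self, x: np.ndarray, dh_seq: np.ndarray, cache):
        """dh_seq: (B, T, H) gradient on every hidden state."""
        b_n, t_n, c_in = x.shape
        hd = self.hidden
        d_wx = np.zeros_like(self.wx)
        d_wh = np.zeros_like(self.wh)
        d_b = np.zeros_like(self.b)
        dh_next = np.zeros((b_n, hd))
        dc_next = np.zeros((b_n, hd))
        for t in range(t_n - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = cache[t]
            dh = dh_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            d_wx += x[:, t].T @ dz
            d_wh += h_prev.T @ dz
            d_b += dz.sum(axis=0)
            dh_next = dz @ self.wh.T
        return [d_wx, d_wh, d_b]


class BiLSTMClassifier:
    """Bidirectional LSTM + fully connected + softmax, trained with Adam."""

    def __init__(self, config: BiLSTMConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.fwd = _LSTMDirection(config.n_channels, config.hidden, rng)
        self.bwd = _LSTMDirection(config.n_channels, config.hidden, rng)
        s = 1.0 / np.sqrt(2 * config.hidden)
        self.w_fc = rng.uniform(-s, s, size=(2 * config.hidden, config.n_classes))
        self.b_fc = np.zeros(config.n_classes)
        self.loss_history: list[float] = []

    # -- parameter plumbing -------------------------------------------------
    def _params(self) -> list[np.ndarray]:
        return self.fwd.params() + self.bwd.params() + [self.w_fc, self.b_fc]

    # -- forward ------------------------------------------------------------
    def _features(self, x: np.ndarray):
        hf, cf = self.fwd.forward(x)
        hb, cb = self.bwd.forward(x[:, ::-1])
        feat = np.concatenate([hf.mean(axis=1), hb.mean(axis=1)], axis=1)
        return feat, (hf, cf, hb, cb)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        feat, _ = self._features(np.asarray(x, dtype=float))
        logits = feat @ self.w_fc + self.b_fc
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # -- training -----------------------------------------------------------
    def _loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        b_n, t_n, _ = x.shape
        feat, (hf, cf, hb, cb) = self._features(x)
        logits = feat @ self.w_fc + self.b_fc
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        loss = -np.log(probs[np.arange(b_n), y] + 1e-12).mean()

        dlogits = probs.copy()
        dlogits[np.arange(b_n), y] -= 1.0
        dlogits /= b_n
        d_wfc = feat.T @ dlogits
        d_bfc = dlogits.sum(axis=0)
        dfeat = dlogits @ self.w_fc.T
        hd = self.config.hidden
        # mean pooling spreads the gradient uniformly over time
        dh_f = np.repeat(dfeat[:, None, :hd], t_n, axis=1) / t_n
        dh_b = np.repeat(dfeat[:, None, hd:], t_n, axis=1) / t_n
        g_f = self.fwd.backward(x, dh_f, cf)
        g_b = self.bwd.backward(x[:, ::-1], dh_b, cb)
        return loss, g_f + g_b + [d_wfc, d_bfc]

    def fit(self, x: np.ndarray, y: np.ndarray) -> "BiLSTMClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(x) == 0:
            raise ValueError("empty training set")
        cfg = self.config
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for epoch in range(1, cfg.epochs + 1):
            loss, grads = self._loss_and_grads(x, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}"
                )
            norm = np.sqrt(sum((g**2).sum() for g in grads))
            scale = min(1.0, cfg.clip_norm / (norm + 1e-12))
            for k, (p, g) in enumerate(zip(params, grads)):
                g = g * scale
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mh = m[k] / (1 - beta1**epoch)
                vh = v[k] / (1 - beta2**epoch)
                p -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
            self.loss_history.append(float(loss))
        return self

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        names = ["fwd_wx", "fwd_wh", "fwd_b", "bwd_wx", "bwd_wh", "bwd_b",
                 "w_fc", "b_fc"]
        np.savez(path.with_suffix(".npz"), **dict(zip(names, self._params())))
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "BiLSTMClassifier":
        path = Path(path)
        cfg = BiLSTMConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        data = np.load(path.with_suffix(".npz"))
        model.fwd.wx, model.fwd.wh, model.fwd.b = (
            data["fwd_wx"], data["fwd_wh"], data["fwd_b"])
        model.bwd.wx, model.bwd.wh, model.bwd.b = (
            data["bwd_wx"], data["bwd_wh"], data["bwd_b"])
        model.w_fc, model.b_fc = data["w_fc"], data["b_fc"]
        return model
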