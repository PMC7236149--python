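"""Minimal convolutional network in NumPy.

Three convolution blocks (3×3 kernels, leaky-ReLU, 2×2 max-pooling,
dropout), two dense layers, and a softmax output trained with categorical
cross-entropy and the Adam optimizer. Sized for small landscape images; the
implementation favors clarity and exact reproducibility (a single seeded
generator drives initialization, shuffling and dropout) over raw speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TinyCNN", "DivergenceError"]


class DivergenceError(RuntimeError):
    """Raised when training produces non-finite losses."""


def _leaky(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x > 0, x, alpha * x)


def _leaky_grad(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x > 0, 1.0, alpha)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 correlation. x (N,H,W,C), w (k,k,C,F) → (N,H,W,F)."""
    k = w.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
    return np.tensordot(cols, w, axes=([3, 4, 5], [2, 0, 1])) + b


def _conv_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    k = w.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
    dw = np.tensordot(cols, dout, axes=([0, 1, 2], [0, 1, 2]))  # (C,k,k,F)
    dw = dw.transpose(1, 2, 0, 3)
    db = dout.sum(axis=(0, 1, 2))
    # dx: full correlation of dout with spatially flipped, channel-swapped w
    w_flip = w[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,F,C)
    dp = np.pad(dout, ((0, 0), (p, p), (p, p), (0, 0)))
    dcols = sliding_window_view(dp, (k, k), axis=(1, 2))
    dx = np.tensordot(dcols, w_flip, axes=([3, 4, 5], [2, 0, 1]))
    return dx, dw, db


def _pool_forward(x: np.ndarray, size: int):
    n, h, w, c = x.shape
    h2, w2 = h // size, w // size
    xt = x[:, : h2 * size, : w2 * size].reshape(n, h2, size, w2, size, c)
    out = xt.max(axis=(2, 4))
    mask = xt == out[:, :, None, :, None, :]
    # break ties: keep only the first maximum within each window
    flat = mask.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, size * size)
    first = np.cumsum(flat, axis=-1) == 1
    flat &= first
    mask = flat.reshape(n, h2, w2, c, size, size).transpose(0, 1, 4, 2, 5, 3)
    return out, (mask, x.shape, size)


def _pool_backward(dout: np.ndarray, cache):
    mask, shape, size = cache
    n, h, w, c = shape
    h2, w2 = h // size, w // size
    dx = np.zeros(shape)
    expanded = mask * dout[:, :, None, :, None, :]
    dx[:, : h2 * size, : w2 * size] = expanded.reshape(n, h2 * size, w2 * size, c)
    return dx


@dataclass
class _Adam:
    lr: float
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, g in grads.items():
            m = self.m.setdefault(key, np.zeros_like(g))
            v = self.v.setdefault(key, np.zeros_like(g))
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class TinyCNN:
    """Conv(3×3)·leaky-ReLU·pool·dropout ×3 → dense ×2 → softmax."""

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        n_classes: int,
        conv_channels: tuple[int, ...] = (32, 64, 128),
        kernel: int = 3,
        pool: int = 2,
        alpha: float = 0.1,
        dropout: float = 0.1,
        dense_sizes: tuple[int, int] = (64, 32),
        seed: int = 0,
    ):
        self.input_shape = input_shape
        self.n_classes = n_classes
        self.conv_channels = tuple(conv_channels)
        self.kernel = kernel
        self.pool = pool
        self.alpha = alpha
        self.dropout = dropout
        self.dense_sizes = tuple(dense_sizes)
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self._build()

    def _build(self) -> None:
        h, w, c = self.input_shape
        cin = c
        for i, cout in enumerate(self.conv_channels):
            fan_in = self.kernel * self.kernel * cin
            self.params[f"Wc{i}"] = self.rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (self.kernel, self.kernel, cin, cout)
            )
            self.params[f"bc{i}"] = np.zeros(cout)
            h, w, cin = h // self.pool, w // self.pool, cout
            if h < 1 or w < 1:
                raise ValueError("input too small for the pooling stack")
        flat = h * w * cin
        sizes = [flat, *self.dense_sizes, self.n_classes]
        for i in range(len(sizes) - 1):
            self.params[f"Wd{i}"] = self.rng.normal(
                0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1])
            )
            self.params[f"bd{i}"] = np.zeros(sizes[i + 1])
        self._n_dense = len(sizes) - 1

    # -- forward/backward -------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool):
        cache: list = []
        h = x
        for i in range(len(self.conv_channels)):
            z = _conv_forward(h, self.params[f"Wc{i}"], self.params[f"bc{i}"])
            a = _leaky(z, self.alpha)
            p, pcache = _pool_forward(a, self.pool)
            if train and self.dropout > 0:
                mask = (self.rng.random(p.shape) >= self.dropout) / (1 - self.dropout)
                p = p * mask
            else:
                mask = None
            cache.append((h, z, pcache, mask))
            h = p
        shape_conv = h.shape
        h = h.reshape(h.shape[0], -1)
        dense_cache: list = []
        for i in range(self._n_dense):
            z = h @ self.params[f"Wd{i}"] + self.params[f"bd{i}"]
            last = i == self._n_dense - 1
            a = z if last else _leaky(z, self.alpha)
            if not last and train and self.dropout > 0:
                mask = (self.rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                a = a * mask
            else:
                mask = None
            dense_cache.append((h, z, mask))
            h = a
        logits = h
        logits = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        return probs, (cache, dense_cache, shape_conv)

    def _backward(self, probs: np.ndarray, y_onehot: np.ndarray, caches):
        cache, dense_cache, shape_conv = caches
        n = probs.shape[0]
        grads: dict[str, np.ndarray] = {}
        delta = (probs - y_onehot) / n
        for i in range(self._n_dense - 1, -1, -1):
            h, z, mask = dense_cache[i]
            grads[f"Wd{i}"] = h.T @ delta
            grads[f"bd{i}"] = delta.sum(axis=0)
            delta = delta @ self.params[f"Wd{i}"].T
            if i > 0:
                _, zprev, maskprev = dense_cache[i - 1]
                if maskprev is not None:
                    delta = delta * maskprev
                delta = delta * _leaky_grad(zprev, self.alpha)
        delta = delta.reshape(shape_conv)
        for i in range(len(self.conv_channels) - 1, -1, -1):
            h, z, pcache, mask = cache[i]
            if mask is not None:
                delta = delta * mask
            delta = _pool_backward(delta, pcache)
            delta = delta * _leaky_grad(z, self.alpha)
            dx, dw, db = _conv_backward(h, self.params[f"Wc{i}"], delta)
            grads[f"Wc{i}"] = dw
            grads[f"bc{i}"] = db
            delta = dx
        return grads

    def loss(self, probs: np.ndarray, y: np.ndarray) -> float:
        n = probs.shape[0]
        return float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))

    # -- training ---------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        lr: float = 1e-3,
        epochs: int = 50,
        batch_size: int = 32,
        patience: int = 5,
    ) -> dict:
        """Mini-batch Adam with early stopping on validation loss.

        Returns the training log; raises :class:`DivergenceError` on
        non-finite losses (e.g. untenable learning rates).
        """
        opt = _Adam(lr=lr)
        n = x.shape[0]
        log = {"train_loss": [], "val_loss": []}
        best_val = np.inf
        best_params = None
        bad = 0
        for _ in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                probs, caches = self._forward(xb, train=True)
                losses.append(self.loss(probs, yb))
                onehot = np.eye(self.n_classes)[yb]
                grads = self._backward(probs, onehot, caches)
                if any(not np.all(np.isfinite(g)) for g in grads.values()):
                    raise DivergenceError("non-finite gradients during training")
                opt.step(self.params, grads)
                if any(np.abs(v).max() > 1e8 for v in self.params.values()):
                    raise DivergenceError("parameter blow-up (>1e8): learning rate untenable")
            train_loss = float(np.mean(losses))
            if not np.isfinite(train_loss):
                raise DivergenceError(f"training loss diverged ({train_loss})")
            log["train_loss"].append(train_loss)
            if x_val is not None and x_val.shape[0] > 0:
                val_loss = self.loss(self.predict_proba(x_val), y_val)
                log["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_params = {k: v.copy() for k, v in self.params.items()}
                    bad = 0
                else:
                    bad += 1
                    if bad > patience:
                        break
        if best_params is not None:
            self.params = best_params
        return log

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = []
        for start in range(0, x.shape[0], batch_size):
            probs, _ = self._forward(x[start : start + batch_size], train=False)
            outs.append(probs)
        return np.concatenate(outs, axis=0)
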