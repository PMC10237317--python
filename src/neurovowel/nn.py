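"""Minimal 2-D convolutional network in NumPy.

A small, fully deterministic CNN (conv -> relu -> maxpool stages, one
hidden dense layer, softmax output) trained with Adam on cross-entropy.
Written for chunk-sized inputs (a handful of frames by a few dozen
frequency bins), where explicit im2col convolution is plenty fast and
the absence of a deep-learning framework dependency keeps the package
light.  All randomness (init, shuffling) flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """[N,C,H,W] -> [N, H'*W', C*kh*kw] patches (valid, stride 1)."""
    n, c, h, w = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, (n, c, oh, ow, kh, kw), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)
        self.k = k
        self.c_in = c_in

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp_shape = xp.shape
        cols = _im2col(xp, k, k)
        self._cols = cols
        n = x.shape[0]
        oh, ow = x.shape[2], x.shape[3]
        y = cols @ self.w.T + self.b
        return y.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c_out, oh, ow = gy.shape
        g = gy.transpose(0, 2, 3, 1).reshape(n, oh * ow, c_out)
        self.gw = np.einsum("npo,npf->of", g, self._cols) / n
        self.gb = g.sum(axis=(0, 1)) / n
        gcols = g @ self.w  # [n, oh*ow, c_in*k*k]
        k, p = self.k, self.k // 2
        _, c_in, hp, wp = self._xp_shape
        gx = np.zeros(self._xp_shape)
        gcols = gcols.reshape(n, oh, ow, c_in, k, k)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + oh, j : j + ow] += gcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return gx[:, :, p : hp - p, p : wp - p]

    def params(self):
        return [(self.w, "gw"), (self.b, "gb")]


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :, : oh * 2, : ow * 2].reshape(n, c, oh, 2, ow, 2)
        xc = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, 4)
        self._arg = xc.argmax(axis=-1)
        return xc.max(axis=-1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, oh, ow = gy.shape
        gflat = np.zeros((n, c, oh, ow, 4))
        np.put_along_axis(gflat, self._arg[..., None], gy[..., None], axis=-1)
        g = gflat.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros(self._in_shape)
        gx[:, :, : oh * 2, : ow * 2] = g.reshape(n, c, oh * 2, ow * 2)
        return gx


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.b = np.zeros(d_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n = gy.shape[0]
        self.gw = self._x.T @ gy / n
        self.gb = gy.mean(axis=0)
        return gy @ self.w.T

    def params(self):
        return [(self.w, "gw"), (self.b, "gb")]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class TrainLog:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


class TinyCNN:
    """conv-relu-pool x2, dense-relu, softmax; Adam on cross-entropy."""

    def __init__(
        self,
        input_shape: tuple[int, int],
        n_classes: int = 5,
        conv_channels: tuple[int, ...] = (16, 32),
        kernel: int = 3,
        dense_units: int = 64,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.input_shape = input_shape
        h, w = input_shape
        self.stages = []
        c_in = 1
        for c_out in conv_channels:
            conv = _Conv(c_in, c_out, kernel, rng)
            self.stages.append((conv, _ReLU(), _MaxPool2()))
            c_in = c_out
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ValueError("input too small for the conv/pool stack")
        self.flat_dim = c_in * h * w
        self.fc1 = _Dense(self.flat_dim, dense_units, rng)
        self.relu_fc = _ReLU()
        self.fc2 = _Dense(dense_units, n_classes, rng)
        self.n_classes = n_classes
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x[:, None, :, :]  # single representation channel
        for conv, relu, pool in self.stages:
            h = pool.forward(relu.forward(conv.forward(h)))
        self._pool_out_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.relu_fc.forward(self.fc1.forward(h))
        return self.fc2.forward(h)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for [N, H, W] (or a single [H, W]) input."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} != expected {self.input_shape}"
            )
        p = softmax(self._forward(x))
        return p[0] if single else p

    def _backward(self, glogits: np.ndarray) -> None:
        g = self.fc2.backward(glogits)
        g = self.fc1.backward(self.relu_fc.backward(g))
        g = g.reshape(self._pool_out_shape)
        for conv, relu, pool in reversed(self.stages):
            g = conv.backward(relu.backward(pool.backward(g)))

    def _layers(self):
        for conv, _, _ in self.stages:
            yield conv
        yield self.fc1
        yield self.fc2

    def _adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        i = 0
        for layer in self._layers():
            for param, gname in layer.params():
                g = getattr(layer, gname)
                if i not in self._adam_state:
                    self._adam_state[i] = (np.zeros_like(param), np.zeros_like(param))
                m, v = self._adam_state[i]
                m[:] = beta1 * m + (1 - beta1) * g
                v[:] = beta2 * v + (1 - beta2) * g * g
                mh = m / (1 - beta1**t)
                vh = v / (1 - beta2**t)
                param -= lr * mh / (np.sqrt(vh) + eps)
                i += 1

    # -- training ------------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ) -> TrainLog:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        n = len(x)
        rng = np.random.default_rng(seed)
        log = TrainLog()
        for _ in range(epochs):
            order = rng.permutation(n)
            total, correct = 0.0, 0
            for s in range(0, n, batch_size):
                idx = order[s : s + batch_size]
                xb, yb = x[idx], y[idx]
                logits = self._forward(xb)
                p = softmax(logits)
                eps = 1e-12
                total += -np.sum(np.log(p[np.arange(len(yb)), yb] + eps))
                correct += int(np.sum(p.argmax(axis=1) == yb))
                g = p.copy()
                g[np.arange(len(yb)), yb] -= 1.0
                self._backward(g)
                self._adam_step(learning_rate)
            log.loss.append(total / n)
            log.accuracy.append(correct / n)
        return log
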