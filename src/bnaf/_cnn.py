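"""Minimal 1-D convolutional network in numpy (forward + backprop + Adam).

Sized for 30-sample signal classification; no GPU framework is assumed. The
two architectures mirror the configured model family: ``simple`` stacks two
convolutions and one pooling layer, ``complex`` four convolutions and two
pooling layers, both followed by one fully connected layer and a 4-way
softmax output.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CNNModel", "build_cnn"]


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv1D(_Layer):
    """Same-padding 1-D convolution, kernel width 3 by default."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        L = x.shape[2]
        self._xw = np.stack([xp[:, :, i : i + L] for i in range(k)], axis=2)
        self._pad, self._L = pad, L
        return np.einsum("ocj,bcjl->bol", self.W, self._xw) + self.b[None, :, None]

    def backward(self, dout):
        self.grads[0][...] = np.einsum("bol,bcjl->ocj", dout, self._xw)
        self.grads[1][...] = dout.sum(axis=(0, 2))
        dxw = np.einsum("ocj,bol->bcjl", self.W, dout)
        B, C = dxw.shape[0], dxw.shape[1]
        dxp = np.zeros((B, C, self._L + 2 * self._pad))
        for j in range(self.kernel):
            dxp[:, :, j : j + self._L] += dxw[:, :, j, :]
        return dxp[:, :, self._pad : self._pad + self._L]


class _ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool1D(_Layer):
    """Width-2 max pooling; a trailing odd sample is dropped."""

    def forward(self, x):
        B, C, L = x.shape
        half = L // 2
        self._shape = x.shape
        xr = x[:, :, : 2 * half].reshape(B, C, half, 2)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dout):
        B, C, L = self._shape
        half = L // 2
        dx = np.zeros((B, C, half, 2))
        np.put_along_axis(dx, self._arg[..., None], dout[..., None], axis=3)
        out = np.zeros(self._shape)
        out[:, :, : 2 * half] = dx.reshape(B, C, 2 * half)
        return out


class _Flatten(_Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNModel:
    """A trainable 1-D CNN classifier over fixed-width input signals."""

    def __init__(self, architecture: str, input_len: int = 30, n_classes: int = 4,
                 kernel: int = 3, hidden: int = 64, seed: int = 0):
        if architecture not in ("simple", "complex"):
            raise ValueError(f"unknown architecture {architecture!r}")
        rng = np.random.default_rng(seed)
        self.architecture = architecture
        self.input_len = input_len
        self.n_classes = n_classes
        layers: list[_Layer] = []
        if architecture == "simple":
            layers += [_Conv1D(1, 16, kernel, rng)]
            layers += [_Conv1D(16, 32, kernel, rng), _ReLU(), _MaxPool1D()]
            flat = 32 * (input_len // 2)
        else:
            layers += [_Conv1D(1, 16, kernel, rng), _ReLU()]
            layers += [_Conv1D(16, 16, kernel, rng), _ReLU(), _MaxPool1D()]
            half = input_len // 2
            layers += [_Conv1D(16, 32, kernel, rng), _ReLU()]
            layers += [_Conv1D(32, 32, kernel, rng), _ReLU(), _MaxPool1D()]
            flat = 32 * (half // 2)
        layers += [_Flatten(), _Dense(flat, hidden, rng), _ReLU(),
                   _Dense(hidden, n_classes, rng)]
        self.layers = layers

    @property
    def n_conv_layers(self) -> int:
        return sum(isinstance(l, _Conv1D) for l in self.layers)

    @property
    def n_pool_layers(self) -> int:
        return sum(isinstance(l, _MaxPool1D) for l in self.layers)

    def _forward(self, X: np.ndarray) -> np.ndarray:
        h = X.reshape(X.shape[0], 1, self.input_len).astype(float)
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self._forward(np.asarray(X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 128,
            batch_size: int = 64, lr: float = 1e-3, seed: int = 0) -> "CNNModel":
        """Minibatch Adam on softmax cross-entropy."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(seed)
        params = [p for l in self.layers for p in l.params]
        grads = [g for l in self.layers for g in l.grads]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(X)
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self._forward(X[idx])
                probs = _softmax(logits)
                dlogits = probs.copy()
                dlogits[np.arange(len(idx)), y[idx]] -= 1.0
                dlogits /= len(idx)
                dout = dlogits
                for layer in reversed(self.layers):
                    dout = layer.backward(dout)
                t += 1
                for i, (p, g) in enumerate(zip(params, grads)):
                    m[i] = b1 * m[i] + (1 - b1) * g
                    v[i] = b2 * v[i] + (1 - b2) * g * g
                    mh = m[i] / (1 - b1**t)
                    vh = v[i] / (1 - b2**t)
                    p -= lr * mh / (np.sqrt(vh) + eps)
        return self

    # -- serialization -----------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for l in self.layers for p in l.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = [p for l in self.layers for p in l.params]
        if len(params) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            p[...] = np.asarray(w).reshape(p.shape)


def build_cnn(architecture: str, input_len: int = 30, n_classes: int = 4,
              seed: int = 0, **kwargs) -> CNNModel:
    """Construct a CNN of the named architecture (``simple`` or ``complex``)."""
    return CNNModel(architecture, input_len=input_len, n_classes=n_classes,
                    seed=seed, **kwargs)
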