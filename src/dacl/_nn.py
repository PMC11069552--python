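"""Minimal dense-network toolkit: explicit forward/backward passes and Adam.

Everything downstream (the autoencoder imputer and the GAN classifier) is a
stack of fully connected layers, so a tiny hand-rolled backprop engine keeps
the package dependency-free and bit-reproducible.  Weights are float64;
initialization is Glorot-uniform from a caller-supplied ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "Adam", "sigmoid", "leaky_relu", "softmax", "bce", "softmax_ce"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def leaky_relu(z: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(z >= 0, z, slope * z)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Dense:
    """One affine layer with an optional elementwise activation.

    ``activation`` is one of ``None`` (identity), ``"sigmoid"``, ``"lrelu"``.
    ``backward`` consumes the gradient w.r.t. the layer output, stores the
    parameter gradients, and returns the gradient w.r.t. the layer input.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 activation: str | None = None):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-limit, limit, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._z: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        self._z = z
        if self.activation == "sigmoid":
            return sigmoid(z)
        if self.activation == "lrelu":
            return leaky_relu(z)
        return z

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        z = self._z
        if self.activation == "sigmoid":
            s = sigmoid(z)
            grad_out = grad_out * s * (1.0 - s)
        elif self.activation == "lrelu":
            grad_out = grad_out * np.where(z >= 0, 1.0, 0.2)
        self.dW = self._x.T @ grad_out
        self.db = grad_out.sum(axis=0)
        return grad_out @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class MLP:
    """A sequential stack of Dense layers sharing one backward pass."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 hidden_activation: str = "lrelu",
                 output_activation: str | None = None):
        self.layers: list[Dense] = []
        for i in range(len(sizes) - 1):
            act = hidden_activation if i < len(sizes) - 2 else output_activation
            self.layers.append(Dense(sizes[i], sizes[i + 1], rng, act))

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    """Adaptive-moment gradient descent over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce(p: np.ndarray, target: np.ndarray | float, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy of probabilities ``p`` against 0/1 targets."""
    p = np.clip(p, eps, 1.0 - eps)
    t = np.broadcast_to(np.asarray(target, dtype=float), p.shape)
    return float(np.mean(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))))


def softmax_ce(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean cross-entropy of row-softmax probabilities against integer labels."""
    return float(np.mean(-np.log(np.clip(probs[np.arange(len(labels)), labels], eps, None))))
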