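"""Minimal trainable-layer framework (numpy).

Only the components the classifier heads need: dense, 1-D batch
normalisation, dropout, ReLU, sigmoid, flatten, the Adam optimiser and
the clipped binary cross-entropy loss.  Every layer implements
``forward(x, training)`` and ``backward(dy)``; parameters and their
gradients are exposed as parallel lists for the optimiser.
"""

from __future__ import annotations

import numpy as np

EPSILON = 1e-7  # probability clipping for the cross-entropy loss


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (in_features + out_features))  # Glorot uniform
        self.w = rng.uniform(-limit, limit, size=(in_features, out_features))
        self.b = np.zeros(out_features)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]


class BatchNorm1d(Layer):
    def __init__(self, num_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(num_features)
        self.beta = np.zeros(num_features)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        self._training = training
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        self.dgamma[...] = (dy * self._xhat).sum(axis=0)
        self.dbeta[...] = dy.sum(axis=0)
        dxhat = dy * self.gamma
        if not self._training or dy.shape[0] == 1:
            # evaluation mode normalises with fixed running statistics, so
            # the layer is affine in x
            return dxhat / self._std
        return (
            dxhat - dxhat.mean(axis=0) - self._xhat * (dxhat * self._xhat).mean(axis=0)
        ) / self._std

    def parameters(self):
        return [self.gamma, self.beta]

    def gradients(self):
        return [self.dgamma, self.dbeta]


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                           np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.gradients()]


class Adam:
    """Adam with bias correction; updates parameters in place."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_loss(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Mean binary cross-entropy with predictions clipped to
    [EPSILON, 1 - EPSILON]; zero iff every clipped prediction matches its
    binary label."""
    y = np.asarray(labels, dtype=float).ravel()
    h = np.asarray(predictions, dtype=float).ravel()
    if y.shape != h.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {h.shape} predictions")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be binary (0/1)")
    h = np.clip(h, EPSILON, 1.0 - EPSILON)
    return float(-np.mean(y * np.log(h) + (1.0 - y) * np.log(1.0 - h)))


def bce_grad(labels: np.ndarray, predictions: np.ndarray) -> np.ndarray:
    """Gradient of the clipped mean BCE w.r.t. the predictions."""
    y = np.asarray(labels, dtype=float).ravel()
    h = np.clip(np.asarray(predictions, dtype=float).ravel(), EPSILON, 1.0 - EPSILON)
    return (h - y) / (h * (1.0 - h)) / y.size
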