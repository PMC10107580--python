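"""Minimal NumPy neural-network layer: MLPs with batch normalisation,
dropout, ReLU and AdamW, trained by mini-batch gradient descent.

This is a small, fully deterministic (seeded) implementation sized for
desk-scale QSAR work: dense layers, manual backpropagation, decoupled weight
decay (AdamW) and per-epoch exponential learning-rate decay. Batch
normalisation keeps running statistics for inference mode, so predictions
after training are pure functions of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class Layer:
    """Forward/backward layer protocol."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He initialisation for ReLU stacks
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class ReLU(Layer):
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm(Layer):
    """Batch normalisation with running statistics for inference."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training_batch = training and x.shape[0] > 1
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        xhat, std = self._xhat, self._std
        self.grads[0][...] = (grad * xhat).sum(axis=0)
        self.grads[1][...] = grad.sum(axis=0)
        gx = grad * self.gamma
        if not self._training_batch:
            return gx / std
        n = grad.shape[0]
        return (gx - gx.mean(axis=0) - xhat * (gx * xhat).mean(axis=0)) / std


class Dropout(Layer):
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def make_mlp(
    n_in: int,
    hidden: tuple[int, ...],
    n_out: int,
    rng: np.random.Generator,
    dropout: float = 0.0,
    batchnorm: bool = True,
) -> Sequential:
    """ReLU MLP with batch normalisation and dropout at every hidden layer."""
    layers: list[Layer] = []
    prev = n_in
    for width in hidden:
        layers.append(Linear(prev, width, rng))
        if batchnorm:
            layers.append(BatchNorm(width))
        layers.append(ReLU())
        if dropout > 0:
            layers.append(Dropout(dropout, rng))
        prev = width
    layers.append(Linear(prev, n_out, rng))
    return Sequential(layers)


class AdamW:
    """Adam with decoupled weight decay and exponential learning-rate decay."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        lr_decay: float = 1.0,
    ):
        self.params = params
        self.lr0 = lr
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.lr_decay = lr_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)

    def end_epoch(self) -> None:
        self.lr *= self.lr_decay


@dataclass
class TrainConfig:
    """Training hyperparameters shared by the MLP and graph-encoder loops."""

    epochs: int = 500
    batch_size: int = 64
    lr: float = 1e-3
    lr_decay: float = 1.0
    weight_decay: float = 0.0
    dropout: float = 0.0
    hidden: tuple[int, ...] = (256, 128)
    seed: int = 0


def iterate_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_mlp(
    x: np.ndarray, y: np.ndarray, config: TrainConfig
) -> tuple[Sequential, list[float]]:
    """Train an MLP regressor on (x, y) under the MSE loss; returns the model
    in inference-ready state and the per-epoch training losses."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    if x.shape[0] < 1:
        raise ValueError("no training data")
    rng = np.random.default_rng(config.seed)
    net = make_mlp(x.shape[1], config.hidden, 1, rng, dropout=config.dropout)
    opt = AdamW(
        net.params,
        lr=config.lr,
        weight_decay=config.weight_decay,
        lr_decay=config.lr_decay,
    )
    losses: list[float] = []
    for _ in range(config.epochs):
        epoch_loss = 0.0
        n_seen = 0
        for idx in iterate_minibatches(x.shape[0], config.batch_size, rng):
            xb, yb = x[idx], y[idx]
            pred = net.forward(xb, training=True)
            diff = pred - yb
            loss = float((diff**2).mean())
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at step {opt.t}")
            net.backward(2.0 * diff / diff.shape[0])
            opt.step(net.grads)
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        opt.end_epoch()
        losses.append(epoch_loss / n_seen)
    return net, losses


def predict_mlp(net: Sequential, x: np.ndarray) -> np.ndarray:
    return net.forward(np.asarray(x, dtype=float), training=False).ravel()
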