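"""Minimal feed-forward neural-network layers with hand-written backprop.

Everything the adversarial deconfounding model needs — fully connected
layers, batch normalization, ReLU, inverted dropout, Adam — implemented on
float32 NumPy arrays.  Layers are stateful: ``forward`` caches what
``backward`` needs, so each layer instance belongs to exactly one network
and is used single-threaded.

Gradients for the loss heads (MSE, binary/categorical cross-entropy on
logits) are computed analytically where the losses are defined, so no
autograd graph is required.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, gradient) triples; gradient arrays are accumulated in place."""
        return []

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        return []


class Linear(Layer):
    """Affine map with He-normal weight init (suits the ReLU networks here)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]


class BatchNorm1d(Layer):
    """Batch normalization over the sample axis.

    Training mode normalizes by batch statistics and updates exponential
    running averages; eval mode uses the running statistics, making the
    forward pass a fixed affine map.
    """

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n, dtype=DTYPE)
        self.beta = np.zeros(n, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            self._cache = (xhat, inv, x.shape[0])
            return self.gamma * xhat + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * ((x - self.running_mean) * inv) + self.beta

    def backward(self, grad):
        xhat, inv, n = self._cache
        self.ggamma += (grad * xhat).sum(axis=0)
        self.gbeta += grad.sum(axis=0)
        gx = self.gamma * grad
        return inv / n * (n * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))

    def parameters(self):
        return [("gamma", self.gamma, self.ggamma), ("beta", self.beta, self.gbeta)]

    def buffers(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Identity(Layer):
    def forward(self, x, training):
        return x

    def backward(self, grad):
        return grad


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend((f"{i}.{n}", v, g) for n, v, g in layer.parameters())
        return out

    def buffers(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend((f"{i}.{n}", v) for n, v in layer.buffers())
        return out

    def zero_grad(self):
        for _, _, g in self.parameters():
            g[...] = 0.0


def mlp(
    dims: list[int],
    rng: np.random.Generator,
    hidden_batchnorm: bool = True,
    hidden_activation: bool = True,
) -> Sequential:
    """Fully connected stack: Linear [+ BatchNorm] [+ ReLU] per hidden layer,
    plain Linear on the output layer."""
    layers: list[Layer] = []
    for i in range(len(dims) - 1):
        layers.append(Linear(dims[i], dims[i + 1], rng))
        if i < len(dims) - 2:
            if hidden_batchnorm:
                layers.append(BatchNorm1d(dims[i + 1]))
            if hidden_activation:
                layers.append(ReLU())
    return Sequential(*layers)


class Adam:
    """Adam with the standard bias correction; one instance per network."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)  # (name, value, grad)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(v) for _, v, _ in self.params]
        self.v = [np.zeros_like(v) for _, v, _ in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (_, val, grad), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (grad - m)
            v += (1.0 - self.b2) * (grad * grad - v)
            val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# --- loss heads (value + gradient w.r.t. logits) ---------------------------


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def bce_with_logits(z: np.ndarray, target: float | np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.ravel()
    t = np.broadcast_to(np.asarray(target, dtype=np.float64), z.shape)
    # log(1+exp(-|z|)) formulation: stable for large |z|
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - t) / z.size).astype(DTYPE)
    return loss, grad.reshape(-1, 1)


def softmax_cross_entropy(z: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy on logits; returns (loss, dloss/dz)."""
    n = z.shape[0]
    zs = z - z.max(axis=1, keepdims=True)
    logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
    loss = float(-logp[np.arange(n), labels].mean())
    grad = softmax(z)
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(DTYPE)
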