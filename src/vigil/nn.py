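"""A small numpy sequential-network engine with manual backpropagation.

Supports exactly what the three classifier families need: dense layers,
dilated (optionally causal) 1-D convolutions, batch normalization, ReLU,
inverted dropout (element-wise and channel-wise), temporal average pooling
and nearest-neighbor upsampling, residual TCN units, the Adam optimizer,
and binary cross-entropy / mean-squared-error losses.

Conventions
-----------
* Sequence tensors are ``(batch, time, channels)``; flat tensors are
  ``(batch, features)``. All math is float32.
* Binary classifiers end in a single linear unit; the sigmoid is folded
  into the loss (``bce_with_logits``) and into ``predict_proba`` for
  numerical stability, which is mathematically identical to a sigmoid
  output layer.
* Layers draw their initial weights from a caller-supplied
  ``numpy.random.Generator``, so construction is reproducible; dropout is
  active only when ``training=True`` is passed through the network.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# layers

class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs; parameters
    and their gradients live in ``params`` / ``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _he_uniform(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Dropout(Layer):
    """Inverted dropout; identity at inference. ``channel_wise`` drops whole
    channels of a (batch, time, channels) sequence for all timesteps (the
    'recurrent-style' second dropout inside TCN residual units)."""

    def __init__(self, rate: float, rng: np.random.Generator,
                 channel_wise: bool = False):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self.channel_wise = channel_wise

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        shape = (x.shape[0], 1, x.shape[2]) if self.channel_wise else x.shape
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Conv1D(Layer):
    """Dilated 1-D convolution on (batch, time, channels), 'same' length.

    ``causal=True`` pads only on the left by (k-1)*dilation, so the output
    at time t depends on inputs at times <= t.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1,
                 causal: bool = True, w_init_std: float | None = None):
        super().__init__()
        self.k = kernel_size
        self.d = dilation
        self.causal = causal
        if w_init_std is None:
            self.params["W"] = _he_uniform(
                rng, (kernel_size, c_in, c_out), kernel_size * c_in
            )
        else:
            # small-normal init (TCN convention); keeps deep residual
            # stacks near-identity at initialization
            self.params["W"] = rng.normal(
                0.0, w_init_std, (kernel_size, c_in, c_out)
            ).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def _padding(self) -> tuple[int, int]:
        total = (self.k - 1) * self.d
        if self.causal:
            return total, 0
        left = total // 2
        return left, total - left

    def forward(self, x, training=False):
        left, right = self._padding()
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        self._xp = xp
        n, T = x.shape[0], x.shape[1]
        W = self.params["W"]
        y = np.broadcast_to(self.params["b"], (n, T, W.shape[2])).copy()
        for i in range(self.k):
            y += xp[:, i * self.d : i * self.d + T, :] @ W[i]
        return y

    def backward(self, dy):
        T = dy.shape[1]
        W = self.params["W"]
        xp = self._xp
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for i in range(self.k):
            sl = slice(i * self.d, i * self.d + T)
            dW[i] = np.einsum("ntc,ntf->cf", xp[:, sl, :], dy)
            dxp[:, sl, :] += dy @ W[i].T
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 1))
        left, right = self._padding()
        return dxp[:, left : xp.shape[1] - right, :]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, time) of a sequence.

    Uses batch statistics while training (with running-average updates)
    and the running statistics at inference, so inference is independent
    of batch composition.
    """

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
            self._norm_n = x.shape[0] * x.shape[1]
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._training = training
        self._xhat, self._inv = xhat, inv
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        if not self._training:
            return dxhat * inv
        m = self._norm_n
        return (
            inv / m * (
                m * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * (dxhat * xhat).sum(axis=(0, 1))
            )
        ).astype(DTYPE)


class AvgPool1D(Layer):
    """Non-overlapping temporal average pooling; time must divide evenly."""

    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x, training=False):
        n, T, c = x.shape
        if T % self.size:
            raise ValueError(
                f"sequence length {T} not divisible by pool size {self.size}"
            )
        self._T = T
        return x.reshape(n, T // self.size, self.size, c).mean(axis=2)

    def backward(self, dy):
        n, t, c = dy.shape
        return np.repeat(dy / self.size, self.size, axis=1)


class NearestUpsample1D(Layer):
    """Nearest-neighbor temporal upsampling by an integer factor."""

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x, training=False):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, dy):
        n, T, c = dy.shape
        return dy.reshape(n, T // self.factor, self.factor, c).sum(axis=2)


class ResidualUnit(Layer):
    """One TCN residual unit at a single dilation (two dilated convolutions
    with optional batch norm, ReLU and dropout, plus a skip connection;
    1x1 convolution on the skip path when channel counts differ).

    ``activation=False`` builds the decoder variant with no ReLU anywhere.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int,
                 rng: np.random.Generator, causal: bool = True,
                 dropout: float = 0.0, recurrent_dropout: float = 0.0,
                 use_batch_norm: bool = True, activation: bool = True):
        super().__init__()
        self.activation = activation

        def conv(ci, co):
            return Conv1D(ci, co, kernel_size, rng, dilation, causal,
                          w_init_std=0.01)

        self.path: list[Layer] = []
        for j, (ci, co) in enumerate([(c_in, c_out), (c_out, c_out)]):
            self.path.append(conv(ci, co))
            if use_batch_norm:
                self.path.append(BatchNorm1D(co))
            if activation:
                self.path.append(ReLU())
            if dropout > 0:
                self.path.append(Dropout(dropout, rng))
            if recurrent_dropout > 0:
                self.path.append(
                    Dropout(recurrent_dropout, rng, channel_wise=True)
                )
        self.skip = (
            Conv1D(c_in, c_out, 1, rng, 1, causal) if c_in != c_out else None
        )
        self.out_relu = ReLU() if activation else None

    def forward(self, x, training=False):
        h = x
        for layer in self.path:
            h = layer.forward(h, training)
        s = self.skip.forward(x, training) if self.skip is not None else x
        y = h + s
        if self.out_relu is not None:
            y = self.out_relu.forward(y, training)
        return y

    def backward(self, dy):
        if self.out_relu is not None:
            dy = self.out_relu.backward(dy)
        dh = dy
        for layer in reversed(self.path):
            dh = layer.backward(dh)
        ds = self.skip.backward(dy) if self.skip is not None else dy
        return dh + ds

    def _sublayers(self):
        out = list(self.path)
        if self.skip is not None:
            out.append(self.skip)
        return out

    @property
    def n_parameters(self):
        return sum(l.n_parameters for l in self._sublayers())


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def _walk(self):
        for layer in self.layers:
            if isinstance(layer, ResidualUnit):
                yield from layer._sublayers()
            elif isinstance(layer, Sequential):
                yield from layer._walk()
            else:
                yield layer

    def parameter_items(self):
        """(layer, name, array) triples for every trainable parameter."""
        for layer in self._walk():
            for name in layer.params:
                yield layer, name, layer.params[name]

    @property
    def n_parameters(self):
        return sum(p.size for _, _, p in self.parameter_items())

    def state(self) -> list[np.ndarray]:
        """Copies of all trainable parameters, in traversal order."""
        return [p.copy() for _, _, p in self.parameter_items()]


# ---------------------------------------------------------------------------
# optimizer and losses

class Adam:
    def __init__(self, net: Sequential, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, _, p in net.parameter_items()]
        self.v = [np.zeros_like(p) for _, _, p in net.parameter_items()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name, p) in enumerate(self.net.parameter_items()):
            g = layer.grads[name]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of logits ``z`` against labels ``y``;
    returns (loss, dloss/dz)."""
    z = z.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - y) / z.size
    return float(loss), dz.astype(DTYPE)


def mse_loss(r: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    diff = r.astype(np.float64) - x
    loss = float(np.mean(diff**2))
    dr = (2.0 * diff / diff.size).astype(DTYPE)
    return loss, dr
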