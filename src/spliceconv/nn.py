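"""Minimal deterministic 1-D CNN engine.

Implements exactly the layer vocabulary the architecture catalog needs —
same-padding 1-D convolution (im2col + GEMM), ReLU/sigmoid/tanh/channel
softmax activations, size-2 stride-1 max/average pooling, global average
pooling, flatten, dense, inverted dropout — with manual backpropagation and
the adam / nadam / sgd / adagrad / rmsprop optimizers.  Everything is
float32, single-threaded-deterministic, and seeded through
``numpy.random.Generator`` streams, so a fixed seed reproduces training
bit-for-bit.

Inputs are (batch, length, channels) tensors; for genomic windows the
channels are the one-hot (A, C, G, T) columns.
"""

from __future__ import annotations

import numpy as np

from .errors import DivergenceError, ShapeError


class Layer:
    """Base layer: stateless unless it declares parameters."""

    name: str = ""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def init(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padding 1-D convolution; optional output stride by subsampling.

    The parameter tensor W has shape (kernel * c_in, c_out) with kernel-major
    row order.  The forward/backward passes avoid an explicit im2col buffer:
    the padded input is multiplied once by a channel-major restack of W
    (one GEMM producing all kernel taps at once) and the taps are then
    summed at their shifted positions, which is substantially cheaper in
    memory traffic than materializing the im2col matrix.

    With same padding, striding the convolution equals computing the full
    stride-1 output and keeping every ``stride``-th position, which is how
    it is implemented here.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, name: str, stride: int = 1):
        if kernel % 2 == 0:
            raise ShapeError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.name = name
        self.W = np.zeros((kernel * c_in, c_out), dtype=np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None
        self._in_len = 0

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.kernel * self.c_in
        std = np.sqrt(2.0 / fan_in)  # He init for the ReLU stack
        self.W = rng.normal(0.0, std, self.W.shape).astype(np.float32)
        self.b = np.zeros(self.c_out, dtype=np.float32)

    def _w_channel_major(self) -> np.ndarray:
        # (kernel*c_in, c_out) k-major -> (c_in, kernel*c_out)
        K, C, F = self.kernel, self.c_in, self.c_out
        return np.ascontiguousarray(
            self.W.reshape(K, C, F).transpose(1, 0, 2).reshape(C, K * F)
        )

    def forward(self, x, train, rng):
        B, L, C = x.shape
        if C != self.c_in:
            raise ShapeError(f"{self.name}: expected {self.c_in} channels, got {C}")
        K, F = self.kernel, self.c_out
        pad = K // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        Lp = L + 2 * pad
        taps = (xp.reshape(B * Lp, C) @ self._w_channel_major()).reshape(B, Lp, K, F)
        y = np.empty((B, L, F), dtype=np.float32)
        y[:] = self.b
        for k in range(K):
            y += taps[:, k : k + L, k, :]
        self._xp = xp if train else None
        self._in_len = L
        if self.stride > 1:
            y = y[:, :: self.stride, :]
        return y

    def backward(self, dy):
        assert self._xp is not None, "backward before forward(train=True)"
        B = dy.shape[0]
        L = self._in_len
        K, C, F = self.kernel, self.c_in, self.c_out
        pad = K // 2
        Lp = L + 2 * pad
        if self.stride > 1:
            full = np.zeros((B, L, F), dtype=np.float32)
            full[:, :: self.stride, :] = dy
            dy = full
        dy = dy.astype(np.float32, copy=False)
        # scatter dy into its K shifted copies, then one GEMM each for dW, dx
        dtaps = np.zeros((B, Lp, K, F), dtype=np.float32)
        for k in range(K):
            dtaps[:, k : k + L, k, :] = dy
        dtaps2 = dtaps.reshape(B * Lp, K * F)
        xp2 = self._xp.reshape(B * Lp, C)
        dw_cm = xp2.T @ dtaps2  # (C, K*F), channel-major
        self.dW = np.ascontiguousarray(
            dw_cm.reshape(C, K, F).transpose(1, 0, 2).reshape(K * C, F)
        )
        self.db = dy.sum(axis=(0, 1))
        dxp = (dtaps2 @ self._w_channel_major().T).reshape(B, Lp, C)
        return dxp[:, pad : pad + L, :]


class Activation(Layer):
    """Elementwise (or channelwise, for softmax) nonlinearity."""

    def __init__(self, kind: str = "relu"):
        if kind not in ("relu", "sigmoid", "tanh", "softmax"):
            raise ShapeError(f"unknown activation {kind!r}")
        self.kind = kind
        self._cache: np.ndarray | None = None

    def forward(self, x, train, rng):
        if self.kind == "relu":
            y = np.maximum(x, 0.0)
        elif self.kind == "sigmoid":
            y = 1.0 / (1.0 + np.exp(-x))
        elif self.kind == "tanh":
            y = np.tanh(x)
        else:  # softmax over the channel axis
            z = x - x.max(axis=-1, keepdims=True)
            e = np.exp(z)
            y = e / e.sum(axis=-1, keepdims=True)
        self._cache = y if train else None
        return y

    def backward(self, dy):
        y = self._cache
        assert y is not None
        if self.kind == "relu":
            return dy * (y > 0)
        if self.kind == "sigmoid":
            return dy * y * (1.0 - y)
        if self.kind == "tanh":
            return dy * (1.0 - y * y)
        dot = (dy * y).sum(axis=-1, keepdims=True)
        return y * (dy - dot)


class _Pool1D(Layer):
    """Size-2 stride-1 pooling that preserves length (last position pools itself)."""

    def __init__(self, pool: int = 2):
        if pool != 2:
            raise ShapeError("only pool size 2 is supported")
        self.pool = pool


class MaxPool1D(_Pool1D):
    def forward(self, x, train, rng):
        B, L, C = x.shape
        y = x.copy()
        right = x[:, 1:, :]
        take_right = np.zeros((B, L, C), dtype=bool)
        take_right[:, : L - 1, :] = right > x[:, : L - 1, :]  # ties go left
        np.maximum(y[:, : L - 1, :], right, out=y[:, : L - 1, :])
        if train:
            self._take_right = take_right
        return y

    def backward(self, dy):
        B, L, C = dy.shape
        tr = self._take_right
        dx = dy * ~tr
        dx[:, 1:, :] += dy[:, : L - 1, :] * tr[:, : L - 1, :]
        return dx


class AvgPool1D(_Pool1D):
    def forward(self, x, train, rng):
        B, L, C = x.shape
        y = x.copy()
        y[:, : L - 1, :] = 0.5 * (x[:, : L - 1, :] + x[:, 1:, :])
        self._L = L
        return y

    def backward(self, dy):
        B, L, C = dy.shape
        dx = np.zeros_like(dy)
        dx[:, : L - 1, :] += 0.5 * dy[:, : L - 1, :]
        dx[:, 1:, :] += 0.5 * dy[:, : L - 1, :]
        dx[:, L - 1, :] += dy[:, L - 1, :]
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x, train, rng):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._L, axis=1) / self._L


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, name: str):
        self.n_in, self.n_out, self.name = n_in, n_out, name
        self.W = np.zeros((n_in, n_out), dtype=np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def init(self, rng):
        std = np.sqrt(2.0 / self.n_in)
        self.W = rng.normal(0.0, std, self.W.shape).astype(np.float32)
        self.b = np.zeros(self.n_out, dtype=np.float32)

    def forward(self, x, train, rng):
        if x.shape[1] != self.n_in:
            raise ShapeError(f"{self.name}: expected {self.n_in} features, got {x.shape[1]}")
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dy):
        assert self._x is not None
        self.dW = (self._x.T @ dy).astype(np.float32, copy=False)
        self.db = dy.sum(axis=0).astype(np.float32, copy=False)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ShapeError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        assert rng is not None, "dropout in training mode needs an RNG"
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Network:
    """A feed-forward layer stack with explicit forward/backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def init(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init(rng)

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Propagate an output gradient back to the input; fills layer grads."""
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> dict[str, np.ndarray]:
        """Flat {layer_name/param: tensor} view of all learnable parameters."""
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            for pname, tensor in layer.params().items():
                out[f"{layer.name}/{pname}"] = tensor
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            for pname, tensor in layer.grads().items():
                out[f"{layer.name}/{pname}"] = tensor
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for pname in layer.params():
                key = f"{layer.name}/{pname}"
                if key in values:
                    current = layer.params()[pname]
                    if current.shape != values[key].shape:
                        raise ShapeError(
                            f"{key}: expected shape {current.shape}, got {values[key].shape}"
                        )
                    setattr(layer, pname, values[key].astype(np.float32).copy())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits.

    ``labels`` are integer class indices.  Raises :class:`DivergenceError`
    when the loss is non-finite.
    """
    if not np.isfinite(logits).all():
        raise DivergenceError("network output contains non-finite values")
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(np.float32).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    if not np.isfinite(loss):
        raise DivergenceError(f"loss diverged to {loss}")
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Optimizer:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def step(self, grads):
        for k, p in self.params.items():
            p -= self.lr * grads[k]


class Adagrad(Optimizer):
    def __init__(self, params, lr, eps=1e-8):
        super().__init__(params, lr)
        self.eps = eps
        self.G = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, grads):
        for k, p in self.params.items():
            self.G[k] += grads[k] ** 2
            p -= self.lr * grads[k] / (np.sqrt(self.G[k]) + self.eps)


class RMSProp(Optimizer):
    def __init__(self, params, lr, rho=0.9, eps=1e-8):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.G = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, grads):
        for k, p in self.params.items():
            self.G[k] = self.rho * self.G[k] + (1 - self.rho) * grads[k] ** 2
            p -= self.lr * grads[k] / (np.sqrt(self.G[k]) + self.eps)


class Adam(Optimizer):
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p) for k, p in params.items()}
        self.v = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            p -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


class Nadam(Adam):
    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1 ** (self.t + 1)
        c1t = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_bar = b1 * self.m[k] / c1 + (1 - b1) * g / c1t
            p -= self.lr * m_bar / (np.sqrt(self.v[k] / c2) + self.eps)


OPTIMIZERS = {
    "sgd": SGD,
    "adam": Adam,
    "adagrad": Adagrad,
    "rmsprop": RMSProp,
    "nadam": Nadam,
}


def make_optimizer(name: str, params: dict[str, np.ndarray], lr: float) -> Optimizer:
    key = name.lower()
    if key not in OPTIMIZERS:
        raise ShapeError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    return OPTIMIZERS[key](params, lr)
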