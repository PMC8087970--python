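"""Deep networks on raw two-lead beats (no feature engineering).

Two architectures classify a raw (V1, V2) beat pair directly:

* a 1-D convolutional network of exactly 15 layers — 1 input, 3 convolution,
  3 batch-normalization, 3 rectified-linear, 2 max-pool, 1 fully connected,
  1 soft-max and 1 classification output layer;
* a bidirectional LSTM network — 1 sequence input, 2 bidirectional LSTM
  hidden layers, 1 fully connected, 1 soft-max and 1 classification output
  layer.

Both consume an ``(n, 2, T)`` tensor (channel 0 = V1, channel 1 = V2) and
emit two class probabilities from the soft-max.  The networks, their
backpropagation and the Adam optimizer are implemented directly in NumPy as
a compact, fully deterministic engine: single-threaded CPU arithmetic with
one seed for initialization and batch shuffling gives bit-reproducible
training.  Analytic gradients are validated against numeric differentiation
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainingLog",
    "ArchitectureError",
    "default_cnn_spec",
    "default_blstm_spec",
    "build_network",
    "train_network",
    "predict_network",
    "Network",
]


class ArchitectureError(ValueError):
    """Raised when a layer list violates an architecture's layer-count contract."""


# required layer-kind counts per architecture
_CNN_COUNTS = {"input": 1, "conv": 3, "batchnorm": 3, "relu": 3,
               "maxpool": 2, "fc": 1, "softmax": 1, "output": 1}
_BLSTM_COUNTS = {"input": 1, "blstm": 2, "fc": 1, "softmax": 1, "output": 1}

_CNN_LAYERS = ("input",
               "conv", "batchnorm", "relu", "maxpool",
               "conv", "batchnorm", "relu", "maxpool",
               "conv", "batchnorm", "relu",
               "fc", "softmax", "output")
_BLSTM_LAYERS = ("input", "blstm", "blstm", "fc", "softmax", "output")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture kind, ordered layer list and per-kind structural knobs."""

    kind: str  # "CNN" | "BLSTM"
    layers: tuple[str, ...]
    hyper: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("CNN", "BLSTM"):
            raise ValueError("kind must be 'CNN' or 'BLSTM'")
        object.__setattr__(self, "hyper", dict(self.hyper))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (package defaults, config-exposed)."""

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    patience: int = 10  # early-stopping patience on validation accuracy

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclass
class TrainingLog:
    """Per-epoch training loss and validation accuracy."""

    epochs: list[dict] = field(default_factory=list)

    def record(self, epoch: int, loss: float, val_accuracy: float | None) -> None:
        self.epochs.append(
            {"epoch": epoch, "loss": loss, "val_accuracy": val_accuracy})


def default_cnn_spec(filters: tuple[int, ...] = (16, 32, 64),
                     kernel_sizes: tuple[int, ...] = (16, 8, 4),
                     pool_size: int = 2) -> NetworkSpec:
    """The default 15-layer convolutional architecture."""
    return NetworkSpec(kind="CNN", layers=_CNN_LAYERS,
                       hyper={"filters": filters, "kernel_sizes": kernel_sizes,
                              "pool_size": pool_size})


def default_blstm_spec(hidden_units: int = 64) -> NetworkSpec:
    """The default bidirectional-LSTM architecture (units per direction)."""
    return NetworkSpec(kind="BLSTM", layers=_BLSTM_LAYERS,
                       hyper={"hidden_units": hidden_units})


def _check_counts(spec: NetworkSpec) -> None:
    required = _CNN_COUNTS if spec.kind == "CNN" else _BLSTM_COUNTS
    counts = {k: spec.layers.count(k) for k in required}
    extra = set(spec.layers) - set(required)
    if extra:
        raise ArchitectureError(
            f"{spec.kind} spec contains unsupported layer kinds {sorted(extra)}")
    for kind, want in required.items():
        if counts[kind] != want:
            raise ArchitectureError(
                f"{spec.kind} spec must contain exactly {want} {kind!r} "
                f"layer(s), found {counts[kind]}")


# ---------------------------------------------------------------------------
# Layers.  Each holds params/grads dicts; forward caches what backward needs.


class _Layer:
    kind = "?"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Input(_Layer):
    """Shape gatekeeper for (batch, channels, T) inputs."""

    kind = "input"

    def __init__(self, n_channels: int, length: int) -> None:
        super().__init__()
        self.n_channels = n_channels
        self.length = length

    def forward(self, x, train):
        if x.ndim != 3 or x.shape[1:] != (self.n_channels, self.length):
            raise ValueError(
                f"expected input of shape (n, {self.n_channels}, "
                f"{self.length}), got {x.shape}")
        return x

    def backward(self, g):
        return g


class _SequenceInput(_Input):
    """Input layer that re-lays (batch, channels, T) as (batch, T, channels)."""

    kind = "input"

    def forward(self, x, train):
        return super().forward(x, train).transpose(0, 2, 1)

    def backward(self, g):
        return g.transpose(0, 2, 1)


class _Conv1d(_Layer):
    kind = "conv"

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k = k
        self.pad = ((k - 1) // 2, k // 2)  # 'same' padding
        scale = np.sqrt(1.0 / (c_in * k))
        self.params = {"W": rng.standard_normal((c_out, c_in, k)) * scale,
                       "b": np.zeros(c_out)}

    def forward(self, x, train):
        W, b = self.params["W"], self.params["b"]
        pl, pr = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        B, C, Tp = xp.shape
        T = x.shape[2]
        s = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, (B, C, T, self.k), (s[0], s[1], s[2], s[2]))
        self._win, self._in_shape = win, x.shape
        return np.einsum("bctk,ock->bot", win, W) + b[None, :, None]

    def backward(self, g):
        W = self.params["W"]
        self.grads["W"] = np.einsum("bctk,bot->ock", self._win, g)
        self.grads["b"] = g.sum(axis=(0, 2))
        B, C, T = self._in_shape
        pl, pr = self.pad
        dxp = np.zeros((B, C, T + pl + pr))
        for i in range(self.k):
            dxp[:, :, i:i + T] += np.einsum("bot,oc->bct", g, W[:, :, i])
        return dxp[:, :, pl:pl + T]


class _BatchNorm1d(_Layer):
    kind = "batchnorm"

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) / std[None, :, None]
        self._xhat, self._std, self._train = xhat, std, train
        return (self.params["gamma"][None, :, None] * xhat
                + self.params["beta"][None, :, None])

    def backward(self, g):
        xhat, std = self._xhat, self._std
        self.grads["gamma"] = (g * xhat).sum(axis=(0, 2))
        self.grads["beta"] = g.sum(axis=(0, 2))
        dxhat = g * self.params["gamma"][None, :, None]
        if not self._train:
            return dxhat / std[None, :, None]
        B, _, T = g.shape
        n = B * T
        s1 = dxhat.sum(axis=(0, 2))[None, :, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2))[None, :, None]
        return (dxhat - s1 / n - xhat * s2 / n) / std[None, :, None]


class _ReLU(_Layer):
    kind = "relu"

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class _MaxPool1d(_Layer):
    kind = "maxpool"

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, train):
        B, C, T = x.shape
        T2 = T // self.size
        xr = x[:, :, :T2 * self.size].reshape(B, C, T2, self.size)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, g):
        B, C, T = self._in_shape
        T2 = g.shape[2]
        onehot = (np.arange(self.size)[None, None, None, :]
                  == self._argmax[..., None])
        dx = np.zeros((B, C, T))
        dx[:, :, :T2 * self.size] = (onehot * g[..., None]).reshape(
            B, C, T2 * self.size)
        return dx


class _Dense(_Layer):
    kind = "fc"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(1.0 / n_in)
        self.params = {"W": rng.standard_normal((n_in, n_out)) * scale,
                       "b": np.zeros(n_out)}

    def forward(self, x, train):
        self._in_shape = x.shape
        xf = x.reshape(x.shape[0], -1)
        self._xf = xf
        return xf @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] = self._xf.T @ g
        self.grads["b"] = g.sum(axis=0)
        return (g @ self.params["W"].T).reshape(self._in_shape)


class _Softmax(_Layer):
    kind = "softmax"

    def forward(self, x, train):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, g):
        # gradients are injected below the softmax (fused with cross-entropy)
        return g


class _Output(_Layer):
    """Classification output: cross-entropy over the soft-max probabilities."""

    kind = "output"

    def forward(self, x, train):
        return x

    def backward(self, g):
        return g

    @staticmethod
    def loss(probs: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(np.log(probs[np.arange(y.size), y] + eps)))

    @staticmethod
    def dlogits(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
        g = probs.copy()
        g[np.arange(y.size), y] -= 1.0
        return g / y.size


class _LSTMDirection:
    """One direction of an LSTM layer (gate order: input, forget, cell, out)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator) -> None:
        self.h = hidden
        sx = np.sqrt(1.0 / n_in)
        sh = np.sqrt(1.0 / hidden)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.params = {"Wx": rng.standard_normal((n_in, 4 * hidden)) * sx,
                       "Wh": rng.standard_normal((hidden, 4 * hidden)) * sh,
                       "b": b}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.h
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        self._cache = []
        xW = x @ Wx  # precompute input contributions for all steps
        for t in range(T):
            z = xW[:, t] + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((x[:, t], h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
            hs[:, t] = h
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        B, T, H = dhs.shape
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.empty((B, T, Wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g**2), do * o * (1 - o)], axis=1)
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _BLSTM(_Layer):
    """Bidirectional LSTM; emits the full sequence or the final summary.

    ``mode='sequence'`` returns (B, T, 2H); ``mode='last'`` returns (B, 2H)
    concatenating the forward direction's last state with the backward
    direction's state at the first time step (each direction's complete pass
    over the series).
    """

    kind = "blstm"

    def __init__(self, n_in: int, hidden: int, mode: str,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.mode = mode
        self.h = hidden
        self.fwd = _LSTMDirection(n_in, hidden, rng)
        self.bwd = _LSTMDirection(n_in, hidden, rng)
        self._sync_params()

    def _sync_params(self) -> None:
        self.params = {f"fwd_{k}": v for k, v in self.fwd.params.items()}
        self.params.update({f"bwd_{k}": v for k, v in self.bwd.params.items()})

    def forward(self, x, train):
        # params dicts may have been rebound by the optimizer/state loader
        for k in self.fwd.params:
            self.fwd.params[k] = self.params[f"fwd_{k}"]
            self.bwd.params[k] = self.params[f"bwd_{k}"]
        self._T = x.shape[1]
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])
        if self.mode == "sequence":
            return np.concatenate([hf, hb[:, ::-1]], axis=2)
        return np.concatenate([hf[:, -1], hb[:, -1]], axis=1)

    def backward(self, g):
        H, T = self.h, self._T
        if self.mode == "sequence":
            dhf = g[:, :, :H]
            dhb = g[:, ::-1, H:]
        else:
            B = g.shape[0]
            dhf = np.zeros((B, T, H))
            dhb = np.zeros((B, T, H))
            dhf[:, -1] = g[:, :H]
            dhb[:, -1] = g[:, H:]
        dx = self.fwd.backward(dhf) + self.bwd.backward(dhb)[:, ::-1]
        self.grads = {f"fwd_{k}": v for k, v in self.fwd.grads.items()}
        self.grads.update({f"bwd_{k}": v for k, v in self.bwd.grads.items()})
        return dx


# ---------------------------------------------------------------------------
# Network assembly, training, prediction.


class Network:
    """An ordered stack of layers with a soft-max head over two classes."""

    def __init__(self, spec: NetworkSpec, layers: list[_Layer],
                 input_length: int, n_channels: int) -> None:
        self.spec = spec
        self.layers = layers
        self.input_length = input_length
        self.n_channels = n_channels

    def enumerate_layers(self) -> tuple[str, ...]:
        """Ordered layer kinds of the built network (for introspection)."""
        return tuple(layer.kind for layer in self.layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray,
                       train: bool = True) -> float:
        probs = self.forward(x, train=train)
        loss = _Output.loss(probs, y)
        g = _Output.dlogits(probs, y)
        # gradients enter below the softmax/output head (fused cross-entropy)
        for layer in reversed(self.layers):
            if layer.kind in ("softmax", "output"):
                continue
            g = layer.backward(g)
        return loss

    def parameters(self) -> list[tuple[_Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def state(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.parameters()]

    def load_state(self, state: Iterable[np.ndarray]) -> None:
        for (layer, name), value in zip(self.parameters(), state):
            layer.params[name] = value.copy()


def build_network(spec: NetworkSpec, input_length: int, n_channels: int = 2,
                  seed: int = 0) -> Network:
    """Instantiate an untrained network from an architecture spec.

    Raises :class:`ArchitectureError` if the spec's layer list violates the
    architecture's layer-count contract.
    """
    if input_length < 16:
        raise ValueError("input_length must be >= 16")
    _check_counts(spec)
    rng = np.random.default_rng(seed)
    layers: list[_Layer] = []

    if spec.kind == "CNN":
        filters = tuple(spec.hyper.get("filters", (16, 32, 64)))
        kernels = tuple(spec.hyper.get("kernel_sizes", (16, 8, 4)))
        pool = int(spec.hyper.get("pool_size", 2))
        c, t = n_channels, input_length
        conv_i = 0
        for kind in spec.layers:
            if kind == "input":
                layers.append(_Input(n_channels, input_length))
            elif kind == "conv":
                layers.append(_Conv1d(c, filters[conv_i], kernels[conv_i], rng))
                c = filters[conv_i]
                conv_i += 1
            elif kind == "batchnorm":
                layers.append(_BatchNorm1d(c))
            elif kind == "relu":
                layers.append(_ReLU())
            elif kind == "maxpool":
                layers.append(_MaxPool1d(pool))
                t = t // pool
            elif kind == "fc":
                layers.append(_Dense(c * t, 2, rng))
            elif kind == "softmax":
                layers.append(_Softmax())
            else:
                layers.append(_Output())
    else:
        hidden = int(spec.hyper.get("hidden_units", 64))
        n_blstm = spec.layers.count("blstm")
        blstm_i = 0
        d = n_channels
        for kind in spec.layers:
            if kind == "input":
                layers.append(_SequenceInput(n_channels, input_length))
            elif kind == "blstm":
                mode = "last" if blstm_i == n_blstm - 1 else "sequence"
                layers.append(_BLSTM(d, hidden, mode, rng))
                d = 2 * hidden
                blstm_i += 1
            elif kind == "fc":
                layers.append(_Dense(d, 2, rng))
            elif kind == "softmax":
                layers.append(_Softmax())
            else:
                layers.append(_Output())

    return Network(spec, layers, input_length, n_channels)


class _Adam:
    def __init__(self, net: Network, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name])
                  for layer, name in net.parameters()]
        self.v = [np.zeros_like(layer.params[name])
                  for layer, name in net.parameters()]

    def step(self) -> None:
        self.t += 1
        for idx, (layer, name) in enumerate(self.net.parameters()):
            g = layer.grads[name]
            self.m[idx] = self.b1 * self.m[idx] + (1 - self.b1) * g
            self.v[idx] = self.b2 * self.v[idx] + (1 - self.b2) * g**2
            mhat = self.m[idx] / (1 - self.b1**self.t)
            vhat = self.v[idx] / (1 - self.b2**self.t)
            layer.params[name] = layer.params[name] - self.lr * mhat / (
                np.sqrt(vhat) + self.eps)


def _check_dataset(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 3 or X.shape[0] != y.size:
        raise ValueError("X must be (n, channels, T) with one label per case")
    if X.shape[0] == 0:
        raise ValueError("dataset is empty")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    return X, y


def train_network(net: Network, X: np.ndarray, y: np.ndarray,
                  config: TrainConfig = TrainConfig(), seed: int = 0,
                  validation: tuple[np.ndarray, np.ndarray] | None = None
                  ) -> tuple[Network, TrainingLog]:
    """Train a network with mini-batch Adam; deterministic given ``seed``.

    When a validation set is supplied, training early-stops after
    ``config.patience`` epochs without a new best validation accuracy and the
    best-scoring parameters are restored.
    """
    X, y = _check_dataset(X, y)
    rng = np.random.default_rng(seed)
    opt = _Adam(net, config.learning_rate)
    log = TrainingLog()
    best_acc = -1.0
    best_state = None
    stale = 0
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            losses.append(net.loss_and_grads(X[batch], y[batch], train=True))
            opt.step()
        val_acc = None
        if validation is not None:
            Xv, yv = validation
            labels, _ = predict_network(net, Xv)
            val_acc = float(np.mean(labels == np.asarray(yv)))
        log.record(epoch, float(np.mean(losses)), val_acc)
        if val_acc is not None:
            if val_acc > best_acc:
                best_acc, best_state, stale = val_acc, net.state(), 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if best_state is not None:
        net.load_state(best_state)
    return net, log


def predict_network(net: Network, X: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and class-1 probabilities for a stack of beat pairs."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1:] != (net.n_channels, net.input_length):
        raise ValueError(
            f"expected input shape (n, {net.n_channels}, {net.input_length}), "
            f"got {X.shape}")
    probs = net.forward(X, train=False)
    return probs.argmax(axis=1).astype(int), probs[:, 1]
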