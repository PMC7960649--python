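"""A compact numpy sequential-network backend for dMVPA.

Implements the layer taxonomy used in small decoding architectures — dense
(perceptron) layers, convolutional filter banks, a simple recurrent cell,
and supporting layers (activation, dropout, flatten, average pooling) — with
SGD (classical or Nesterov momentum) and Adam optimizers, trained by
mini-batch backpropagation against categorical cross-entropy.

Everything runs single-threaded on the CPU with one seeded generator driving
weight initialization, batch shuffling, and dropout masks, so runs are
bit-reproducible given a training seed.  Examples keep their full feature
rank: a (channels, timepoints) example reaches a conv layer un-flattened, so
filter shape choices retain their spatiotemporal meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["LayerSpec", "SequentialNet", "build_network", "leaky_relu"]


# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------


def leaky_relu(x: np.ndarray, slope: float = 0.3) -> np.ndarray:
    """f(x) = x for x >= 0, slope * x otherwise."""
    return np.where(x >= 0, x, slope * x)


def _act_forward(name, x, slope):
    if name == "linear":
        return x
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "leaky_relu":
        return leaky_relu(x, slope)
    if name == "tanh":
        return np.tanh(x)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    raise ValueError(f"unknown activation {name!r}")


def _act_backward(name, x, out, grad, slope):
    if name == "linear":
        return grad
    if name == "relu":
        return grad * (x > 0)
    if name == "leaky_relu":
        return grad * np.where(x >= 0, 1.0, slope)
    if name == "tanh":
        return grad * (1.0 - out**2)
    if name == "sigmoid":
        return grad * out * (1.0 - out)
    raise ValueError(f"unknown activation {name!r}")


_ACTIVATIONS = ("linear", "relu", "leaky_relu", "tanh", "sigmoid", "softmax")
LAYER_KINDS = ("dense", "conv", "recurrent", "dropout", "flatten", "activation", "pool")
DEFAULT_LEAKY_SLOPE = 0.3


@dataclass
class LayerSpec:
    """Declarative description of one layer.

    ``kind`` is one of dense / conv / recurrent / dropout / flatten /
    activation / pool; ``params`` hold the kind-specific settings (dense:
    units; conv: filters + kernel; recurrent: cells; dropout: rate;
    activation: name [+ slope]; pool: size).  Dense and conv layers accept an
    inline ``activation`` applied after their primary operation.
    """

    kind: str
    params: dict = field(default_factory=dict)
    activation: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; choose from {LAYER_KINDS}")
        if self.activation is not None and self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.kind == "dropout":
            rate = self.params.get("rate", 0.3)
            if not 0 <= rate < 1:
                raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")

    @classmethod
    def from_dict(cls, d: dict) -> "LayerSpec":
        d = dict(d)
        kind = d.pop("kind", None)
        if kind is None:
            raise ValueError(f"layer spec missing 'kind': {d}")
        activation = d.pop("activation", None)
        return cls(kind=kind, params=d, activation=activation)


class BuildError(ValueError):
    """Layer chain incompatible with the input shape; names the offending layer."""


# ---------------------------------------------------------------------------
# Layer implementations.  Each layer exposes build(shape, rng) -> out shape,
# forward(x, train, rng), backward(grad), and params/grads lists.
# ---------------------------------------------------------------------------


class _Layer:
    params: list = []
    grads: list = []

    def build(self, shape, rng):
        raise NotImplementedError

    def forward(self, x, train, rng):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class _Dense(_Layer):
    def __init__(self, units, activation, slope, index):
        self.units = int(units)
        self.activation = activation or "linear"
        self.slope = slope
        self.index = index

    def build(self, shape, rng):
        if len(shape) != 1:
            raise BuildError(
                f"dense layer {self.index}: input has feature rank {len(shape)}; "
                "insert a flatten layer first"
            )
        fan_in = shape[0]
        limit = np.sqrt(6.0 / (fan_in + self.units))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(fan_in, self.units))
        self.b = np.zeros(self.units)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        return (self.units,)

    def forward(self, x, train, rng):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "softmax":
            self._z = z
            return z  # fused with the loss; net applies softmax at the output
        self._z = z
        self._out = _act_forward(self.activation, z, self.slope)
        return self._out

    def backward(self, grad):
        if self.activation != "softmax":
            grad = _act_backward(self.activation, self._z, self._out, grad, self.slope)
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class _Conv(_Layer):
    """Valid-mode convolution (cross-correlation) with stride 1.

    Accepts a rank-1 input (length,) or rank-2 input as either (length,
    channels) output of a previous conv, or a raw (d1, d2) example treated as
    a 2-D single-channel field.  The kernel rank decides: a rank-2 kernel on
    a rank-2 channelless input convolves over both axes.
    """

    def __init__(self, filters, kernel, activation, slope, index):
        self.filters = int(filters)
        self.kernel = tuple(int(k) for k in (kernel if hasattr(kernel, "__len__") else (kernel,)))
        if len(self.kernel) not in (1, 2):
            raise BuildError(f"conv layer {index}: only 1-D and 2-D kernels supported")
        self.activation = activation or "linear"
        self.slope = slope
        self.index = index

    def build(self, shape, rng):
        kr = len(self.kernel)
        if kr > len(shape):
            raise BuildError(
                f"conv layer {self.index}: kernel rank {kr} exceeds input "
                f"feature rank {len(shape)}"
            )
        # decide spatial dims vs channels
        if kr == 1:
            if len(shape) == 1:
                self.spatial, self.channels = (shape[0],), 1
            elif len(shape) == 2:
                self.spatial, self.channels = (shape[0],), shape[1]
            else:
                raise BuildError(
                    f"conv layer {self.index}: 1-D kernel on rank-{len(shape)} input"
                )
        else:
            if len(shape) == 2:
                self.spatial, self.channels = shape, 1
            elif len(shape) == 3:
                self.spatial, self.channels = shape[:2], shape[2]
            else:
                raise BuildError(
                    f"conv layer {self.index}: 2-D kernel on rank-{len(shape)} input"
                )
        out_spatial = tuple(s - k + 1 for s, k in zip(self.spatial, self.kernel))
        if any(o < 1 for o in out_spatial):
            raise BuildError(
                f"conv layer {self.index}: kernel {self.kernel} larger than "
                f"input spatial extent {self.spatial}"
            )
        fan_in = int(np.prod(self.kernel)) * self.channels
        limit = np.sqrt(6.0 / (fan_in + self.filters))
        self.W = rng.uniform(-limit, limit, size=(*self.kernel, self.channels, self.filters))
        self.b = np.zeros(self.filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._in_rank = len(shape)
        return (*out_spatial, self.filters)

    def forward(self, x, train, rng):
        n = x.shape[0]
        if len(self.kernel) == 1:
            xc = x[..., None] if self._in_rank == 1 else x  # (n, L, C)
            self._xc = xc
            win = sliding_window_view(xc, self.kernel[0], axis=1)  # (n, L', C, k)
            z = np.einsum("nlck,kcf->nlf", win, self.W) + self.b
        else:
            xc = x[..., None] if self._in_rank == 2 else x  # (n, H, W, C)
            self._xc = xc
            win = sliding_window_view(xc, self.kernel, axis=(1, 2))  # (n,H',W',C,kh,kw)
            z = np.einsum("nijcab,abcf->nijf", win, self.W) + self.b
        self._z = z
        if self.activation == "softmax":
            raise BuildError(f"conv layer {self.index}: softmax is not a conv activation")
        self._out = _act_forward(self.activation, z, self.slope)
        return self._out

    def backward(self, grad):
        grad = _act_backward(self.activation, self._z, self._out, grad, self.slope)
        xc = self._xc
        if len(self.kernel) == 1:
            k = self.kernel[0]
            win = sliding_window_view(xc, k, axis=1)
            self.grads[0][...] = np.einsum("nlck,nlf->kcf", win, grad)
            self.grads[1][...] = grad.sum(axis=(0, 1))
            dx = np.zeros_like(xc)
            Lp = grad.shape[1]
            for t in range(k):
                dx[:, t : t + Lp, :] += np.einsum("nlf,cf->nlc", grad, self.W[t])
            return dx[..., 0] if self._in_rank == 1 else dx
        kh, kw = self.kernel
        win = sliding_window_view(xc, self.kernel, axis=(1, 2))
        self.grads[0][...] = np.einsum("nijcab,nijf->abcf", win, grad)
        self.grads[1][...] = grad.sum(axis=(0, 1, 2))
        dx = np.zeros_like(xc)
        Hp, Wp = grad.shape[1], grad.shape[2]
        for a in range(kh):
            for b_ in range(kw):
                dx[:, a : a + Hp, b_ : b_ + Wp, :] += np.einsum(
                    "nijf,cf->nijc", grad, self.W[a, b_]
                )
        return dx[..., 0] if self._in_rank == 2 else dx


class _Recurrent(_Layer):
    """Minimal simple-recurrent (Elman) cell, tanh state, final state as output.

    Consumes a (timesteps, features) example and emits the last hidden state,
    so the surrounding network stays feedforward/sequential.
    """

    def __init__(self, cells, index):
        self.cells = int(cells)
        self.index = index

    def build(self, shape, rng):
        if len(shape) != 2:
            raise BuildError(
                f"recurrent layer {self.index}: needs (timesteps, features) "
                f"input, got feature rank {len(shape)}"
            )
        T, F = shape
        lim_x = np.sqrt(6.0 / (F + self.cells))
        lim_h = np.sqrt(6.0 / (2 * self.cells))
        self.Wx = rng.uniform(-lim_x, lim_x, size=(F, self.cells))
        self.Wh = rng.uniform(-lim_h, lim_h, size=(self.cells, self.cells))
        self.b = np.zeros(self.cells)
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._T = T
        return (self.cells,)

    def forward(self, x, train, rng):
        n, T, _ = x.shape
        self._x = x
        self._h = np.zeros((T + 1, n, self.cells))
        for t in range(T):
            self._h[t + 1] = np.tanh(x[:, t] @ self.Wx + self._h[t] @ self.Wh + self.b)
        return self._h[-1]

    def backward(self, grad):
        x, h = self._x, self._h
        n, T, _ = x.shape
        for g in self.grads:
            g[...] = 0.0
        dx = np.zeros_like(x)
        dh = grad
        for t in range(T - 1, -1, -1):
            dz = dh * (1.0 - h[t + 1] ** 2)
            self.grads[0] += x[:, t].T @ dz
            self.grads[1] += h[t].T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
        return dx


class _Dropout(_Layer):
    def __init__(self, rate):
        self.rate = float(rate)

    def build(self, shape, rng):
        return shape

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class _Flatten(_Layer):
    def build(self, shape, rng):
        self._shape = shape
        return (int(np.prod(shape)),)

    def forward(self, x, train, rng):
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], *self._shape)


class _Activation(_Layer):
    def __init__(self, name, slope, index):
        if name not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {name!r}")
        self.name = name
        self.slope = slope
        self.index = index

    def build(self, shape, rng):
        return shape

    def forward(self, x, train, rng):
        self._x = x
        if self.name == "softmax":
            return x  # terminal softmax is fused with the loss
        self._out = _act_forward(self.name, x, self.slope)
        return self._out

    def backward(self, grad):
        if self.name == "softmax":
            return grad
        return _act_backward(self.name, self._x, self._out, grad, self.slope)


class _Pool(_Layer):
    """Non-overlapping average pooling over the spatial axes of a conv output."""

    def __init__(self, size, index):
        self.size = tuple(int(s) for s in (size if hasattr(size, "__len__") else (size,)))
        self.index = index

    def build(self, shape, rng):
        if len(shape) != len(self.size) + 1:
            raise BuildError(
                f"pool layer {self.index}: size {self.size} incompatible with "
                f"input feature rank {len(shape)} (expects spatial axes + channels)"
            )
        self._in_shape = shape
        out = tuple(s // p for s, p in zip(shape, self.size))
        if any(o < 1 for o in out):
            raise BuildError(f"pool layer {self.index}: pool size {self.size} too large")
        return (*out, shape[-1])

    def forward(self, x, train, rng):
        self._x_shape = x.shape
        if len(self.size) == 1:
            (p,) = self.size
            L = (x.shape[1] // p) * p
            self._L = L
            xt = x[:, :L].reshape(x.shape[0], L // p, p, x.shape[-1])
            return xt.mean(axis=2)
        ph, pw = self.size
        H = (x.shape[1] // ph) * ph
        W = (x.shape[2] // pw) * pw
        self._HW = (H, W)
        xt = x[:, :H, :W].reshape(x.shape[0], H // ph, ph, W // pw, pw, x.shape[-1])
        return xt.mean(axis=(2, 4))

    def backward(self, grad):
        dx = np.zeros(self._x_shape)
        if len(self.size) == 1:
            (p,) = self.size
            dx[:, : self._L] = np.repeat(grad, p, axis=1) / p
            return dx
        ph, pw = self.size
        H, W = self._HW
        up = np.repeat(np.repeat(grad, ph, axis=1), pw, axis=2) / (ph * pw)
        dx[:, :H, :W] = up
        return dx


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------


class _SGD:
    def __init__(self, lr=0.01, momentum=0.9, nesterov=True):
        self.lr, self.momentum, self.nesterov = lr, momentum, nesterov
        self._v = None

    def step(self, params, grads):
        if self._v is None:
            self._v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self._v):
            v *= self.momentum
            v -= self.lr * g
            if self.nesterov:
                p += self.momentum * v - self.lr * g
            else:
                p += v


class _Adam:
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self._m = self._v = None
        self._t = 0

    def step(self, params, grads):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self._t)
            vhat = v / (1 - self.b2**self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _make_optimizer(spec: dict):
    spec = dict(spec or {"kind": "sgd"})
    kind = spec.pop("kind", "sgd")
    if kind == "sgd":
        return _SGD(
            lr=spec.get("lr", 0.01),
            momentum=spec.get("momentum", 0.9),
            nesterov=spec.get("nesterov", True),
        )
    if kind == "adam":
        return _Adam(lr=spec.get("lr", 0.001))
    raise ValueError(f"unknown optimizer {kind!r}; choose sgd or adam")


# ---------------------------------------------------------------------------
# Sequential network
# ---------------------------------------------------------------------------


def _build_layer(ls: LayerSpec, index: int) -> _Layer:
    p = ls.params
    slope = p.get("slope", DEFAULT_LEAKY_SLOPE)
    if ls.kind == "dense":
        return _Dense(p["units"], ls.activation, slope, index)
    if ls.kind == "conv":
        return _Conv(p["filters"], p["kernel"], ls.activation, slope, index)
    if ls.kind == "recurrent":
        return _Recurrent(p["cells"], index)
    if ls.kind == "dropout":
        return _Dropout(p.get("rate", 0.3))
    if ls.kind == "flatten":
        return _Flatten()
    if ls.kind == "activation":
        return _Activation(p["name"], p.get("slope", DEFAULT_LEAKY_SLOPE), index)
    if ls.kind == "pool":
        return _Pool(p["size"], index)
    raise ValueError(f"unknown layer kind {ls.kind!r}")


class SequentialNet:
    """An ordered layer stack trained by mini-batch backpropagation.

    The output layer must end in a softmax (inline on the final dense layer
    or as a terminal activation layer) of width ``n_classes``; the softmax is
    fused with the categorical cross-entropy loss for a numerically stable
    gradient.
    """

    def __init__(self, layer_specs, input_shape, n_classes, optimizer=None,
                 epochs=50, batch_size=32, seed=0):
        self.layer_specs = list(layer_specs)
        self.input_shape = tuple(input_shape)
        self.n_classes = int(n_classes)
        self.optimizer_spec = dict(optimizer or {"kind": "sgd"})
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.seed = int(seed)
        self.history: dict[str, list[float]] = {}
        self._built = False

    # -- construction ------------------------------------------------------

    def build(self, rng=None):
        rng = rng or np.random.default_rng(np.random.SeedSequence([self.seed]))
        for i, ls in enumerate(self.layer_specs[:-1]):
            if ls.activation == "softmax" or (
                ls.kind == "activation" and ls.params.get("name") == "softmax"
            ):
                raise BuildError(f"layer {i}: softmax is only valid as the final layer")
        self.layers = [_build_layer(ls, i) for i, ls in enumerate(self.layer_specs)]
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.build(shape, rng)
        last = self.layer_specs[-1]
        terminal_softmax = (last.kind == "dense" and last.activation == "softmax") or (
            last.kind == "activation" and last.params.get("name") == "softmax"
        )
        if not terminal_softmax:
            raise BuildError(
                "network must end in a softmax output (inline on the final "
                "dense layer or as a terminal activation layer)"
            )
        if shape != (self.n_classes,):
            raise BuildError(
                f"final layer output shape {shape} does not match "
                f"n_classes={self.n_classes}"
            )
        self._built = True
        return self

    # -- forward / loss ----------------------------------------------------

    def _logits(self, X, train, rng):
        out = X
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def predict_scores(self, X):
        X = np.asarray(X, dtype=float)
        logits = self._logits(X, train=False, rng=None)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    @staticmethod
    def _ce_loss(logits, y):
        z = logits - logits.max(axis=1, keepdims=True)
        log_norm = np.log(np.exp(z).sum(axis=1))
        return float(np.mean(log_norm - z[np.arange(len(y)), y]))

    def evaluate(self, X, y):
        logits = self._logits(np.asarray(X, dtype=float), train=False, rng=None)
        loss = self._ce_loss(logits, y)
        acc = float(np.mean(logits.argmax(axis=1) == y))
        return loss, acc

    # -- training ----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        if not self._built:
            self.build()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
        n = len(X)
        onehot = np.zeros((n, self.n_classes))
        onehot[np.arange(n), y] = 1.0
        opt = _make_optimizer(self.optimizer_spec)
        params = [p for lay in self.layers for p in lay.params]
        grads = [g for lay in self.layers for g in lay.grads]
        hist = {"loss": [], "accuracy": []}
        if X_val is not None and len(X_val):
            hist["val_loss"], hist["val_accuracy"] = [], []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            epoch_correct = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                logits = self._logits(xb, train=True, rng=rng)
                loss = self._ce_loss(logits, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/Inf loss at epoch {epoch}, batch starting {start}; "
                        f"logit range [{np.nanmin(logits):.3g}, "
                        f"{np.nanmax(logits):.3g}] — try a lower learning rate"
                    )
                z = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(z)
                p = e / e.sum(axis=1, keepdims=True)
                gout = (p - onehot[idx]) / len(idx)
                for layer in reversed(self.layers):
                    gout = layer.backward(gout)
                opt.step(params, grads)
                epoch_loss += loss * len(idx)
                epoch_correct += int((logits.argmax(axis=1) == yb).sum())
            hist["loss"].append(epoch_loss / n)
            hist["accuracy"].append(epoch_correct / n)
            if X_val is not None and len(X_val):
                vl, va = self.evaluate(X_val, y_val)
                hist["val_loss"].append(vl)
                hist["val_accuracy"].append(va)
        self.history = hist
        return self

    # -- serialization -----------------------------------------------------

    def weight_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lay in enumerate(self.layers):
            for j, p in enumerate(lay.params):
                out[f"layer{i}_param{j}"] = p
        return out

    def set_weight_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, lay in enumerate(self.layers):
            for j, p in enumerate(lay.params):
                p[...] = arrays[f"layer{i}_param{j}"]


def build_network(layer_specs, input_shape, n_classes, optimizer=None,
                  epochs=50, batch_size=32, seed=0) -> SequentialNet:
    """Construct and shape-check a :class:`SequentialNet` (weights initialized)."""
    net = SequentialNet(layer_specs, input_shape, n_classes, optimizer,
                        epochs, batch_size, seed)
    return net.build()
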