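"""The small 2D convolutional classifier for DDE grids.

The default architecture consumes the DDE profile as a tensor of spatial
extent 1x20 with 20 channels and stacks three blocks of

    Conv2D(3x3, same padding) -> LeakyReLU(0.3) -> MaxPool(1x2, ceil) -> Dropout(0.4)

with 32, 64 and 128 filters, followed by Flatten, a 128-unit dense layer
(LeakyReLU + Dropout) and a 2-class softmax head.  Width halves
20 -> 10 -> 5 -> 3 (the last pooling window is partial and kept), so the
flattened feature has 1*3*128 = 384 elements and the network carries
147,682 trainable parameters in total.

The network is implemented directly on numpy: im2col convolutions, explicit
backward passes and standard first-order optimizers (Adam by default).
The model is small enough that this trains in seconds to minutes on one CPU
core.  Analytic shape and parameter traces (:func:`shape_trace`,
:func:`total_param_count`) are derived from the declarative
:class:`ArchitectureSpec` independently of the realized weight arrays, so
tests can cross-check the two routes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ddecnn.errors import (
    ConfigurationError,
    DivergenceError,
    IncompatibleModelError,
)

# ---------------------------------------------------------------------------
# Declarative specs


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of the conv/pool/dense stack.

    ``conv_filters`` may be empty, in which case the dense head sits directly
    on the flattened input.  Pooling is fixed at (1, 2) with stride (1, 2)
    and ceil-mode boundary handling (a partial final window is kept).
    ``dropout_rates`` has one entry per conv block plus one after the dense
    layer; ``None`` means 0.4 everywhere.
    """

    conv_filters: tuple[int, ...] = (32, 64, 128)
    kernel: tuple[int, int] = (3, 3)
    dense_units: int = 128
    n_classes: int = 2
    dropout_rates: tuple[float, ...] | None = None
    activation: str = "leaky_relu"
    leaky_slope: float = 0.3
    input_height: int = 1
    input_width: int = 20
    input_channels: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_filters", tuple(int(f) for f in self.conv_filters))
        object.__setattr__(self, "kernel", tuple(int(k) for k in self.kernel))
        if any(f <= 0 for f in self.conv_filters):
            raise ConfigurationError("conv filter counts must be positive")
        if len(self.kernel) != 2 or any(k < 1 or k % 2 == 0 for k in self.kernel):
            raise ConfigurationError("kernel must be an odd (height, width) pair")
        if self.dense_units < 1 or self.n_classes < 2:
            raise ConfigurationError("dense_units >= 1 and n_classes >= 2 required")
        rates = self.dropout_rates
        if rates is None:
            rates = (0.4,) * (len(self.conv_filters) + 1)
        rates = tuple(float(r) for r in rates)
        if len(rates) != len(self.conv_filters) + 1:
            raise ConfigurationError(
                "need one dropout rate per conv block plus one after the dense layer"
            )
        if any(not (0.0 <= r < 1.0) for r in rates):
            raise ConfigurationError("dropout rates must lie in [0, 1)")
        object.__setattr__(self, "dropout_rates", rates)
        if self.activation not in ("leaky_relu", "relu"):
            raise ConfigurationError("activation must be 'leaky_relu' or 'relu'")
        if min(self.input_height, self.input_width, self.input_channels) < 1:
            raise ConfigurationError("input extents must be positive")
        shape_trace(self)  # fail fast on a spec whose trace degenerates

    @property
    def slope(self) -> float:
        return self.leaky_slope if self.activation == "leaky_relu" else 0.0


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; defaults follow the reference protocol."""

    learning_rate: float = 0.001
    optimizer: str = "adam"
    epochs: int = 80
    batch_size: int = 32
    seed: int = 0
    validation_fraction: float = 0.0
    loss: str = "categorical_crossentropy"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.optimizer not in _OPTIMIZERS:
            raise ConfigurationError(
                f"unknown optimizer {self.optimizer!r}; choose from {sorted(_OPTIMIZERS)}"
            )
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ConfigurationError("validation_fraction must lie in [0, 1)")
        if self.loss != "categorical_crossentropy":
            raise ConfigurationError("only categorical cross-entropy is supported")


# ---------------------------------------------------------------------------
# Analytic shape and parameter traces


def _ceil_half(w: int) -> int:
    return -(-w // 2)


def shape_trace(spec: ArchitectureSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Per-layer output shapes, (height, width, channels) until the flatten.

    Same-padded convolutions preserve the spatial extent; each pooling layer
    halves the width with ceiling rounding (20 -> 10 -> 5 -> 3 for the
    default three blocks).
    """
    h, w, c = spec.input_height, spec.input_width, spec.input_channels
    trace: list[tuple[str, tuple[int, ...]]] = [("input", (h, w, c))]
    for k, f in enumerate(spec.conv_filters, start=1):
        c = f
        trace.append((f"conv2d_{k}", (h, w, c)))
        trace.append((f"activation_{k}", (h, w, c)))
        w = _ceil_half(w)
        if h < 1 or w < 1:
            raise ConfigurationError("pooling exhausted the spatial extent")
        trace.append((f"max_pooling2d_{k}", (h, w, c)))
        trace.append((f"dropout_{k}", (h, w, c)))
    flat = h * w * c
    trace.append(("flatten", (flat,)))
    trace.append(("dense_1", (spec.dense_units,)))
    trace.append(("activation_dense", (spec.dense_units,)))
    trace.append(("dropout_dense", (spec.dense_units,)))
    trace.append(("dense_2", (spec.n_classes,)))
    return trace


def flatten_size(spec: ArchitectureSpec) -> int:
    """Number of elements entering the dense head."""
    return next(s[0] for name, s in shape_trace(spec) if name == "flatten")


def layer_param_count(
    kind: str,
    *,
    filters: int = 0,
    kernel: tuple[int, int] = (3, 3),
    in_channels: int = 0,
    units: int = 0,
    inputs: int = 0,
) -> int:
    """Trainable parameters of a single layer.

    Convolution: filters * (kh*kw*in_channels + 1); dense: units * (inputs + 1);
    activations, pooling, dropout and flatten carry none.
    """
    if kind == "conv":
        return filters * (kernel[0] * kernel[1] * in_channels + 1)
    if kind == "dense":
        return units * (inputs + 1)
    if kind in ("activation", "pool", "dropout", "flatten", "input"):
        return 0
    raise ValueError(f"unknown layer kind {kind!r}")


def param_trace(spec: ArchitectureSpec) -> list[tuple[str, int]]:
    """Per-layer parameter counts aligned with :func:`shape_trace`."""
    out: list[tuple[str, int]] = []
    in_c = spec.input_channels
    for k, f in enumerate(spec.conv_filters, start=1):
        out.append((f"conv2d_{k}", layer_param_count(
            "conv", filters=f, kernel=spec.kernel, in_channels=in_c)))
        in_c = f
    out.append(("dense_1", layer_param_count(
        "dense", units=spec.dense_units, inputs=flatten_size(spec))))
    out.append(("dense_2", layer_param_count(
        "dense", units=spec.n_classes, inputs=spec.dense_units)))
    return out


def total_param_count(spec: ArchitectureSpec) -> int:
    """Total trainable parameters (147,682 for the default architecture)."""
    return sum(n for _, n in param_trace(spec))


# ---------------------------------------------------------------------------
# Layers


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Extract same-padded kh x kw patches; (N, C*kh*kw, H*W)."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((n, c, kh, kw, h, w), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
    return cols.reshape(n, c * kh * kw, h * w)


def _col2im(dcols: np.ndarray, xshape: tuple, kh: int, kw: int) -> np.ndarray:
    n, c, h, w = xshape
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, kh, kw, h, w)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
    return dxp[:, :, ph:ph + h, pw:pw + w]


class _Conv2D:
    def __init__(self, in_c: int, out_c: int, kh: int, kw: int, rng: np.random.Generator):
        fan_in, fan_out = in_c * kh * kw, out_c * kh * kw
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        self.w = rng.uniform(-limit, limit, size=(out_c, in_c * kh * kw))
        self.b = np.zeros(out_c)
        self.kh, self.kw = kh, kw
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        cols = _im2col(x, self.kh, self.kw)          # (N, K, L)
        n, _, h, w = x.shape
        flat = cols.transpose(1, 0, 2).reshape(cols.shape[1], -1)  # (K, N*L)
        out = (self.w @ flat).reshape(-1, n, h * w).transpose(1, 0, 2)
        out += self.b[None, :, None]
        self._cache = (x.shape, flat)
        return out.reshape(n, -1, h, w)

    def backward(self, g):
        xshape, flat = self._cache
        n, _, h, w = xshape
        gf = g.reshape(n, -1, h * w).transpose(1, 0, 2).reshape(g.shape[1], -1)
        self.gw = gf @ flat.T
        self.gb = gf.sum(axis=1)
        dflat = self.w.T @ gf                         # (K, N*L)
        dcols = dflat.reshape(-1, n, h * w).transpose(1, 0, 2)
        return _col2im(dcols, xshape, self.kh, self.kw)

    @property
    def grads(self):
        return [self.gw, self.gb]


class _LeakyReLU:
    params: list = []
    grads: list = []

    def __init__(self, slope: float):
        self.slope = slope

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class _MaxPoolWidth2:
    """Max pooling with window (1, 2), stride (1, 2), ceil-mode boundaries."""

    params: list = []
    grads: list = []

    def forward(self, x, training=False, rng=None):
        n, c, h, w = x.shape
        wo = _ceil_half(w)
        if w % 2:
            x = np.pad(x, ((0, 0), (0, 0), (0, 0), (0, 1)),
                       constant_values=-np.inf)
        r = x.reshape(n, c, h, wo, 2)
        self._arg = r.argmax(axis=-1)
        self._in_w = w
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, wo = g.shape
        dr = np.zeros((n, c, h, wo, 2), dtype=g.dtype)
        np.put_along_axis(dr, self._arg[..., None], g[..., None], axis=-1)
        dx = dr.reshape(n, c, h, 2 * wo)
        return dx[..., : self._in_w]


class _Dropout:
    params: list = []
    grads: list = []

    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_out, n_in))
        self.b = np.zeros(n_out)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, g):
        self.gw = g.T @ self._x
        self.gb = g.sum(axis=0)
        return g @ self.w

    @property
    def grads(self):
        return [self.gw, self.gb]


# ---------------------------------------------------------------------------
# Optimizers


class _SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


class _Adam:
    def __init__(self, lr: float, b1=0.9, b2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = self.v = None

    def step(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class _Nadam(_Adam):
    def step(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c1n = 1 - self.b1 ** (self.t + 1)
        c2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            m_hat = self.b1 * m / c1n + (1 - self.b1) * g / c1
            p -= self.lr * m_hat / (np.sqrt(v / c2) + self.eps)


class _RMSprop:
    def __init__(self, lr: float, rho=0.9, eps=1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = None

    def step(self, params, grads):
        if self.v is None:
            self.v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self.v):
            v *= self.rho
            v += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


class _Adadelta:
    def __init__(self, lr: float, rho=0.95, eps=1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = self.u = None

    def step(self, params, grads):
        if self.v is None:
            self.v = [np.zeros_like(p) for p in params]
            self.u = [np.zeros_like(p) for p in params]
        for p, g, v, u in zip(params, grads, self.v, self.u):
            v *= self.rho
            v += (1 - self.rho) * g * g
            dx = np.sqrt((u + self.eps) / (v + self.eps)) * g
            u *= self.rho
            u += (1 - self.rho) * dx * dx
            p -= self.lr * dx


_OPTIMIZERS = {
    "sgd": _SGD,
    "adam": _Adam,
    "nadam": _Nadam,
    "rmsprop": _RMSprop,
    "adadelta": _Adadelta,
}


# ---------------------------------------------------------------------------
# The network


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNClassifier:
    """A realized (trainable) network built from an ArchitectureSpec.

    Weight initialization is Glorot-uniform, seeded; all layer shapes match
    the analytic :func:`shape_trace` by construction.
    """

    def __init__(self, spec: ArchitectureSpec, config: TrainingConfig):
        self.spec = spec
        self.config = config
        rng = np.random.default_rng(config.seed)
        kh, kw = spec.kernel
        self.layers: list = []
        in_c = spec.input_channels
        for k, f in enumerate(spec.conv_filters):
            self.layers += [
                _Conv2D(in_c, f, kh, kw, rng),
                _LeakyReLU(spec.slope),
                _MaxPoolWidth2(),
                _Dropout(spec.dropout_rates[k]),
            ]
            in_c = f
        self.layers.append(_Flatten())
        flat = flatten_size(spec)
        self.layers += [
            _Dense(flat, spec.dense_units, rng),
            _LeakyReLU(spec.slope),
            _Dropout(spec.dropout_rates[-1]),
            _Dense(spec.dense_units, spec.n_classes, rng),
        ]
        self._init_snapshot = [p.copy() for p in self.parameters()]

    # -- introspection ----------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def trainable_parameter_count(self) -> int:
        """Framework-side counter; must equal :func:`total_param_count`."""
        return sum(p.size for p in self.parameters())

    # -- forward / backward ------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        expect = (self.spec.input_channels, self.spec.input_height, self.spec.input_width)
        if x.ndim != 4 or x.shape[1:] != expect:
            raise ValueError(
                f"input tensors must have shape (n, {expect[0]}, {expect[1]}, "
                f"{expect[2]}); got {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    # -- loss ---------------------------------------------------------------
    @staticmethod
    def loss_and_grad(logits: np.ndarray, y: np.ndarray):
        p = _softmax(logits)
        n = logits.shape[0]
        eps = 1e-12
        loss = -np.log(p[np.arange(n), y] + eps).mean()
        grad = p.copy()
        grad[np.arange(n), y] -= 1.0
        return loss, grad / n

    # -- user-facing --------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray,
            x_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None) -> pd.DataFrame:
        """Seeded minibatch training; one history row per epoch."""
        x = self._check_input(x)
        y = np.asarray(y, dtype=np.int64)
        if len(x) != len(y):
            raise ValueError("features and labels must have equal length")
        if y.min() < 0 or y.max() >= self.spec.n_classes:
            raise ValueError("labels outside [0, n_classes)")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        if x_val is None and cfg.validation_fraction > 0:
            n_val = max(1, int(round(cfg.validation_fraction * len(x))))
            perm = rng.permutation(len(x))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            x, y, x_val, y_val = x[tr_idx], y[tr_idx], x[val_idx], y[val_idx]
        opt = _OPTIMIZERS[cfg.optimizer](cfg.learning_rate)
        history: dict[str, list] = {
            "epoch": [], "train_loss": [], "train_acc": [],
            "val_loss": [], "val_acc": [],
        }
        n = len(x)
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(n)
            total_loss = 0.0
            correct = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = self.forward(x[idx], training=True, rng=rng)
                loss, grad = self.loss_and_grad(logits, y[idx])
                if not np.isfinite(loss):
                    raise DivergenceError(epoch)
                self.backward(grad)
                opt.step(self.parameters(), self.gradients())
                total_loss += loss * len(idx)
                correct += int((logits.argmax(axis=1) == y[idx]).sum())
            history["epoch"].append(epoch)
            history["train_loss"].append(total_loss / n)
            history["train_acc"].append(correct / n)
            if x_val is not None:
                logits = self.forward(np.asarray(x_val, dtype=np.float64))
                vloss, _ = self.loss_and_grad(logits, np.asarray(y_val, dtype=np.int64))
                history["val_loss"].append(float(vloss))
                history["val_acc"].append(
                    float((logits.argmax(axis=1) == np.asarray(y_val)).mean()))
            else:
                history["val_loss"].append(np.nan)
                history["val_acc"].append(np.nan)
        return pd.DataFrame(history)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities; rows are non-negative and sum to one."""
        return _softmax(self.forward(self._check_input(x)))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reuse it safely."""

    model: CNNClassifier
    history: pd.DataFrame
    train_ids: tuple[str, ...] | None = None
    feature_meta: dict = field(default_factory=dict)

    @property
    def spec(self) -> ArchitectureSpec:
        return self.model.spec

    @property
    def config(self) -> TrainingConfig:
        return self.model.config

    @property
    def seed(self) -> int:
        return self.model.config.seed


# ---------------------------------------------------------------------------
# Module-level operations


def build_model(spec: ArchitectureSpec, config: TrainingConfig) -> CNNClassifier:
    """Realize an untrained, seeded network from the declarative spec."""
    return CNNClassifier(spec, config)


def train(
    model: CNNClassifier,
    features: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig | None = None,
    train_ids: Sequence[str] | None = None,
    feature_meta: dict | None = None,
) -> TrainedModel:
    """Fit the network and return it wrapped with its history and metadata.

    ``config`` defaults to the config the model was built with; passing a
    different one rebuilds the optimizer settings but keeps the weights.
    """
    if config is not None and config != model.config:
        model.config = config
    history = model.fit(features, labels)
    changed = any(
        not np.array_equal(p, q)
        for p, q in zip(model.parameters(), model._init_snapshot)
    )
    if not changed:
        raise RuntimeError("training left all weights at their initial values")
    return TrainedModel(
        model=model,
        history=history,
        train_ids=tuple(train_ids) if train_ids is not None else None,
        feature_meta=dict(feature_meta or {}),
    )


def _unwrap(model) -> CNNClassifier:
    return model.model if isinstance(model, TrainedModel) else model


def predict_proba(model, features: np.ndarray) -> np.ndarray:
    return _unwrap(model).predict_proba(features)


def predict_label(model, features: np.ndarray) -> np.ndarray:
    return _unwrap(model).predict(features)


# ---------------------------------------------------------------------------
# Persistence: a model directory with a JSON spec, npz weights and TSV history


def save_model(trained: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "architecture": dataclasses.asdict(trained.spec),
        "training": dataclasses.asdict(trained.config),
        "feature_meta": trained.feature_meta,
        "train_ids": list(trained.train_ids) if trained.train_ids is not None else None,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2) + "\n")
    params = trained.model.parameters()
    np.savez(path / "weights.npz", **{f"param_{k}": p for k, p in enumerate(params)})
    trained.history.to_csv(path / "history.tsv", sep="\t", index=False)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta_file = path / "model.json"
    weight_file = path / "weights.npz"
    if not meta_file.exists() or not weight_file.exists():
        raise FileNotFoundError(f"{path} is not a model directory")
    meta = json.loads(meta_file.read_text())
    arch = dict(meta["architecture"])
    arch["conv_filters"] = tuple(arch["conv_filters"])
    arch["kernel"] = tuple(arch["kernel"])
    if arch.get("dropout_rates") is not None:
        arch["dropout_rates"] = tuple(arch["dropout_rates"])
    spec = ArchitectureSpec(**arch)
    config = TrainingConfig(**meta["training"])
    model = CNNClassifier(spec, config)
    with np.load(weight_file) as data:
        params = model.parameters()
        if len(data.files) != len(params):
            raise IncompatibleModelError(
                f"weights file holds {len(data.files)} arrays, spec expects {len(params)}"
            )
        for k, p in enumerate(params):
            stored = data[f"param_{k}"]
            if stored.shape != p.shape:
                raise IncompatibleModelError(
                    f"weight {k} has shape {stored.shape}, spec expects {p.shape}"
                )
            p[...] = stored
    history = pd.read_csv(path / "history.tsv", sep="\t")
    return TrainedModel(
        model=model,
        history=history,
        train_ids=tuple(meta["train_ids"]) if meta.get("train_ids") else None,
        feature_meta=meta.get("feature_meta", {}),
    )
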