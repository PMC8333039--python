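"""Classifiers: small 1D CNNs and the reading-time threshold baseline.

The CNNs are compact convolutional stacks operating on a single input
channel (the fixed-length representation vector):

    [conv(1x3, same) -> batch norm -> ReLU -> max pool(1x2, stride 2)] x n
    -> flatten -> dense(hidden) -> ReLU -> dense(2) -> softmax

with n = 2, 3 or 4 convolutional layers holding 8, 16, 32, 64 kernels
respectively, trained with stochastic gradient descent with momentum on
the cross-entropy loss.  The networks are implemented directly in numpy
(forward and backward passes written out), which keeps the package
dependency-light and training fully deterministic under a seed; the
models involved are small enough that a CPU matmul path is entirely
adequate.

The baseline classifier thresholds the per-subject reading time: readers
slower than the threshold are called high-risk.  The threshold is the
exhaustive-search accuracy maximiser over midpoints of adjacent sorted
reading times.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ValidationError

#: HR is the positive class (detecting an at-risk reader is a "positive").
LABEL_TO_INDEX = {"LR": 0, "HR": 1}
INDEX_TO_LABEL = {v: k for k, v in LABEL_TO_INDEX.items()}

_KERNEL_COUNTS = (8, 16, 32, 64)


@dataclass(frozen=True)
class CnnSpec:
    """Architecture hyper-parameters; only the depth varies between models."""

    n_conv_layers: int
    kernel_size: int = 3
    pool_size: int = 2
    fc_hidden: int = 64

    def __post_init__(self) -> None:
        if self.n_conv_layers not in (2, 3, 4):
            raise ConfigError("n_conv_layers must be 2, 3 or 4")

    @property
    def n_kernels(self) -> tuple[int, ...]:
        return _KERNEL_COUNTS[: self.n_conv_layers]

    @classmethod
    def from_name(cls, name: str) -> "CnnSpec":
        name = name.lower()
        if name not in ("cnn2", "cnn3", "cnn4"):
            raise ConfigError(f"unknown architecture {name!r}")
        return cls(n_conv_layers=int(name[-1]))


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 16
    max_epochs: int = 100
    early_stopping_patience: int = 15
    input_norm: str = "zscore"  # per-feature, fitted on the training split
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ConfigError("initial_lr must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.input_norm not in ("zscore", "zerocenter", "none"):
            raise ConfigError("input_norm must be zscore, zerocenter or none")


# ---------------------------------------------------------------------------
# layers


class _Conv1d:
    """1x3 convolution with 'same' zero padding, stride 1, via im2col matmul."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = rng.normal(0.0, scale, (c_out, c_in * k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (B, C, L) -> (C*k, B*L) so the convolution is one large GEMM
        B, C, L = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        cols = np.empty((C, self.k, B, L), dtype=x.dtype)
        for i in range(self.k):
            cols[:, i, :, :] = xp[:, :, i : i + L].transpose(1, 0, 2)
        return cols.reshape(C * self.k, B * L)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, _, L = x.shape
        self._shape = (B, L)
        cols = self._im2col(x)
        self._cols = cols if training else None
        y = self.W @ cols  # (C_out, B*L)
        y = y.reshape(-1, B, L).transpose(1, 0, 2)
        return y + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, _, L = dy.shape
        dy2 = np.ascontiguousarray(dy.transpose(1, 0, 2)).reshape(-1, B * L)
        self.dW = dy2 @ self._cols.T
        self.db = dy2.sum(axis=1)
        dcols = (self.W.T @ dy2).reshape(self.c_in, self.k, B, L)
        pad = self.k // 2
        dxp = np.zeros((B, self.c_in, L + 2 * pad), dtype=np.float32)
        for i in range(self.k):
            dxp[:, :, i : i + L] += dcols[:, i].transpose(1, 0, 2)
        return dxp[:, :, pad : pad + L]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class _BatchNorm1d:
    """Per-channel batch normalisation over (batch, position)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean[None, :, None]) * self._inv_std[None, :, None]
            return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None]) * inv[None, :, None]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = dy.shape
        m = B * L
        self.dgamma = (dy * self._xhat).sum(axis=(0, 2))
        self.dbeta = dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True)
        return (self._inv_std[None, :, None] / m) * (
            m * dxhat - s1 - self._xhat * s2
        )

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class _ReLU:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class _MaxPool1d:
    """Size-2, stride-2 max pooling; a trailing odd sample is dropped."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        L = x.shape[2]
        Lo = L // 2
        self._in_len = L
        a = x[:, :, 0 : 2 * Lo : 2]
        b = x[:, :, 1 : 2 * Lo : 2]
        self._left_wins = a >= b  # ties resolve to the left position
        return np.where(self._left_wins, a, b)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, Lo = dy.shape
        dx = np.zeros((B, C, self._in_len), dtype=np.float32)
        dx[:, :, 0 : 2 * Lo : 2] = dy * self._left_wins
        dx[:, :, 1 : 2 * Lo : 2] = dy * ~self._left_wins
        return dx

    def params(self):
        return []

    def grads(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)

    def params(self):
        return []

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model


class Cnn1d:
    """A depth-2/3/4 convolutional classifier for fixed-length signals."""

    def __init__(self, spec: CnnSpec, input_length: int, seed: int = 0):
        if input_length < 2**spec.n_conv_layers:
            raise ConfigError(
                f"input length {input_length} cannot survive "
                f"{spec.n_conv_layers} poolings (needs >= {2**spec.n_conv_layers})"
            )
        self.spec = spec
        self.input_length = input_length
        self.input_mean: np.ndarray | None = None
        self.input_scale: np.ndarray | None = None
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.layers: list = []
        c_in, L = 1, input_length
        for c_out in spec.n_kernels:
            self.layers.append(_Conv1d(c_in, c_out, spec.kernel_size, rng))
            self.layers.append(_BatchNorm1d(c_out))
            self.layers.append(_ReLU())
            self.layers.append(_MaxPool1d())
            c_in, L = c_out, L // spec.pool_size
        self.conv_out_length = L
        self.layers.append(_Flatten())
        self.layers.append(_Dense(c_in * L, spec.fc_hidden, rng))
        self.layers.append(_ReLU())
        self.layers.append(_Dense(spec.fc_hidden, 2, rng))

    # -- plumbing ----------------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(int(p.size) for layer in self.layers for p in layer.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for p in layer.params():
                p[...] = next(it)

    def state_dict(self) -> dict:
        state = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        for j, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm1d):
                state[f"bn{j}_mean"] = layer.running_mean.copy()
                state[f"bn{j}_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        n = sum(len(layer.params()) for layer in self.layers)
        self.set_weights([state[f"w{i}"] for i in range(n)])
        for j, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm1d):
                layer.running_mean[...] = state[f"bn{j}_mean"]
                layer.running_var[...] = state[f"bn{j}_var"]

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        """Logits for a (batch, length) float array."""
        if x.shape[1] != self.input_length:
            raise ValidationError(
                f"input length {x.shape[1]} does not match model "
                f"input length {self.input_length}"
            )
        x = x.astype(np.float32)
        if self.input_mean is not None:
            x = (x - self.input_mean) / self.input_scale
        h = x[:, None, :]  # (B, 1, L)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, X: np.ndarray, batch_size: int = 128) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = [
            _softmax(self.forward(X[i : i + batch_size], training=False))
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(out, axis=0)


def build_cnn(spec: CnnSpec | str, input_length: int, seed: int = 0) -> Cnn1d:
    """Instantiate a CNN for representation vectors of ``input_length``."""
    if isinstance(spec, str):
        spec = CnnSpec.from_name(spec)
    return Cnn1d(spec, input_length, seed=seed)


def _accuracy(model: Cnn1d, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(model.predict_proba(X).argmax(axis=1) == y))


def train_cnn(
    model: Cnn1d,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig | None = None,
) -> dict:
    """SGD-with-momentum training; keeps the best-validation-accuracy weights.

    Returns a history dict with per-epoch training loss and validation
    accuracy plus the best epoch.  Fully deterministic under
    ``cfg.seed`` (weight initialisation is the model's own seed).
    """
    cfg = cfg or TrainConfig()
    X_train = np.asarray(X_train, dtype=np.float32)
    X_val = np.asarray(X_val, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training set must contain both classes")

    if cfg.input_norm != "none":
        mu = X_train.mean(axis=0)
        if cfg.input_norm == "zscore":
            sd = X_train.std(axis=0)
            sd = np.where(sd < 1e-8, 1.0, sd)
        else:
            sd = np.ones_like(mu)
        model.input_mean = mu.astype(np.float32)
        model.input_scale = sd.astype(np.float32)

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    velocity = [np.zeros_like(p) for layer in model.layers for p in layer.params()]

    history = {"train_loss": [], "val_accuracy": [], "best_epoch": -1}
    best_acc, best_state, patience_left = -1.0, None, cfg.early_stopping_patience
    n = len(X_train)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            logits = model.forward(xb, training=True)
            probs = _softmax(logits)
            eps = 1e-12
            epoch_loss += -float(
                np.log(probs[np.arange(len(yb)), yb] + eps).sum()
            )
            dlogits = probs
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            model.backward(dlogits)
            i = 0
            for layer in model.layers:
                for p, g in zip(layer.params(), layer.grads()):
                    velocity[i] = cfg.momentum * velocity[i] - cfg.initial_lr * g
                    p += velocity[i]
                    i += 1
        history["train_loss"].append(epoch_loss / n)
        val_acc = _accuracy(model, X_val, y_val) if len(X_val) else float("nan")
        history["val_accuracy"].append(val_acc)
        if len(X_val) and val_acc > best_acc:
            best_acc = val_acc
            best_state = copy.deepcopy(model.state_dict())
            history["best_epoch"] = epoch
            patience_left = cfg.early_stopping_patience
        elif len(X_val):
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def predict(model: Cnn1d, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (argmax) and softmax probabilities for each row of X."""
    probs = model.predict_proba(np.asarray(X))
    return probs.argmax(axis=1), probs


# ---------------------------------------------------------------------------
# reading-time threshold baseline


@dataclass
class ThresholdModel:
    """Single reading-time cut-off: slower than ``threshold`` means HR."""

    threshold: float
    polarity: str = "above_is_hr"
    train_accuracy: float = field(default=float("nan"))

    def predict(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return np.where(times > self.threshold, "HR", "LR")


def fit_reading_time_threshold(times, labels) -> ThresholdModel:
    """Exhaustive accuracy-maximising threshold over adjacent-time midpoints.

    Candidates are the midpoints between adjacent sorted unique reading
    times plus one candidate below the minimum (everyone HR) and one
    above the maximum (everyone LR); ties in accuracy resolve to the
    smallest threshold.
    """
    times = np.asarray(times, dtype=float)
    labels = np.asarray(labels)
    if len(times) != len(labels) or len(times) == 0:
        raise ValidationError("times and labels must be equal-length and non-empty")
    if not np.all(np.isfinite(times)):
        raise ValidationError("reading times must be finite")
    classes = set(np.unique(labels))
    if classes != {"HR", "LR"}:
        raise ValidationError("both classes HR and LR must be present")
    is_hr = labels == "HR"
    u = np.unique(times)
    candidates = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    best_thr, best_acc = None, -1.0
    for thr in candidates:  # ascending; strict > keeps the smallest tie
        acc = float(np.mean((times > thr) == is_hr))
        if acc > best_acc:
            best_acc, best_thr = acc, float(thr)
    return ThresholdModel(threshold=best_thr, train_accuracy=best_acc)


def save_model(model: Cnn1d, path: str) -> None:
    """Persist weights (+BN statistics, input stats) as .npz with a JSON sidecar."""
    import json
    import os

    state = model.state_dict()
    if model.input_mean is not None:
        state["input_mean"] = model.input_mean
        state["input_scale"] = model.input_scale
    np.savez(path if path.endswith(".npz") else path + ".npz", **state)
    base = path[:-4] if path.endswith(".npz") else path
    sidecar = {
        "n_conv_layers": model.spec.n_conv_layers,
        "kernel_size": model.spec.kernel_size,
        "pool_size": model.spec.pool_size,
        "fc_hidden": model.spec.fc_hidden,
        "input_length": model.input_length,
        "normalized_input": model.input_mean is not None,
    }
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path: str) -> Cnn1d:
    """Rebuild a saved CNN; inverse of :func:`save_model`."""
    import json

    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        meta = json.load(fh)
    spec = CnnSpec(
        n_conv_layers=meta["n_conv_layers"],
        kernel_size=meta["kernel_size"],
        pool_size=meta["pool_size"],
        fc_hidden=meta["fc_hidden"],
    )
    model = Cnn1d(spec, meta["input_length"])
    with np.load(base + ".npz") as data:
        state = {k: data[k] for k in data.files}
    if meta["normalized_input"]:
        model.input_mean = state.pop("input_mean")
        model.input_scale = state.pop("input_scale")
    model.load_state_dict(state)
    return model
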