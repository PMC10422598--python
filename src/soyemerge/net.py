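"""Growth-stage classifier: an improved AlexNet implemented in NumPy.

The network keeps AlexNet's 5-conv / 3-pool / 3-FC silhouette but shrinks the
convolution kernels from 7 to 5 to 3, halves the feature maps with
overlapping max pooling (window 3, stride 2) after conv layers 1, 2 and 5,
and replaces the classic 4096-wide fully connected head with 1024 and 256
units, each under dropout 0.6, ending in a 3-way softmax over the VE/VC/V1
stages. Local response normalisation follows the first two conv layers and
all convolutions slide at stride 1 with same padding.

Everything — convolution, LRN, pooling, dropout, Adam, softmax
cross-entropy and backpropagation — is implemented here on float32 NumPy
arrays, with numba-jitted kernels for the convolution/LRN/pooling hot loops
(pure-NumPy fallbacks give identical results) and reusable scratch buffers,
so the 255x255 input resolution stays tractable on a single CPU.

Training bookkeeping follows the average-loss / average-accuracy convention:
``AL = e_L / e`` and ``AA = (e_A / e) x 100%`` where ``e_L`` and ``e_A`` are
the sums of per-epoch test loss and accuracy over ``e`` epochs, and model
accuracy is ``A = N_C / N_T`` (correctly classified over total).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "NetConfig",
    "TrainConfig",
    "TrainingHistory",
    "EvalResult",
    "Model",
    "build_model",
    "train",
    "average_metrics",
    "evaluate",
    "classify_crops",
]


@dataclass
class NetConfig:
    """Architecture parameters of the improved AlexNet."""

    input_shape: tuple[int, int, int] = (255, 255, 3)
    conv_kernels: tuple[int, ...] = (7, 5, 3, 3, 3)
    conv_channels: tuple[int, ...] = (32, 64, 96, 96, 64)
    pool_layers: tuple[int, ...] = (1, 2, 5)  # 1-based conv layers followed by a pool
    pool_window: int = 3
    pool_stride: int = 2
    fc_sizes: tuple[int, int] = (1024, 256)
    n_classes: int = 3
    dropout: float = 0.6
    lrn: bool = True

    def validate(self) -> None:
        if len(self.conv_kernels) != 5 or len(self.conv_channels) != 5:
            raise ValueError("expected 5 conv kernel sizes and 5 channel counts")
        if len(self.fc_sizes) != 2:
            raise ValueError("expected exactly 2 hidden FC sizes")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.pool_window <= self.pool_stride - 1:
            raise ValueError("pooling must overlap: window > stride - 1")

    @classmethod
    def desk_scale(cls) -> "NetConfig":
        """Reduced-channel preset sized for single-CPU training.

        Architecture (kernel schedule, pooling placement, FC head, LRN,
        dropout) is unchanged; only the feature-map widths shrink.
        """
        return cls(conv_channels=(2, 4, 6, 6, 4))


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 150  # full-scale default; desk-scale runs use ~20
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be positive")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "TrainConfig":
        """Training preset for the reduced-channel net on small datasets.

        The narrow net sees far fewer optimiser steps than a full-scale run,
        so the learning rate is raised to 1e-3; batch size stays at 32.
        """
        return cls(learning_rate=1e-3, batch_size=32, epochs=20, seed=seed)


@dataclass
class TrainingHistory:
    """Per-epoch test loss/accuracy records."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)

    @property
    def e(self) -> int:
        return len(self.loss)

    @property
    def e_L(self) -> float:
        return float(sum(self.loss))

    @property
    def e_A(self) -> float:
        return float(sum(self.accuracy))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(1, self.e + 1),
            "loss": self.loss,
            "accuracy": self.accuracy,
            "train_loss": self.train_loss if len(self.train_loss) == self.e
            else [float("nan")] * self.e,
        })


def average_metrics(history: TrainingHistory) -> tuple[float, float]:
    """Average loss AL = e_L / e and average accuracy AA = (e_A / e) x 100%."""
    if history.e == 0:
        raise ValueError("empty history")
    return history.e_L / history.e, (history.e_A / history.e) * 100.0


@dataclass
class EvalResult:
    accuracy: float            # A = N_C / N_T
    n_correct: int
    n_total: int
    per_class_accuracy: tuple[float, ...]
    confusion: np.ndarray      # rows = true class, cols = predicted


# ---------------------------------------------------------------------------
# layers
#
# Layers keep shape-keyed scratch buffers (_buf) so the large per-batch
# arrays are allocated once and reused across steps; repeated fresh
# multi-megabyte allocations dominate the runtime otherwise.


def _buf(cache: dict, name: str, shape: tuple, dtype=np.float32) -> np.ndarray:
    key = (name, shape, np.dtype(dtype).str)
    arr = cache.get(key)
    if arr is None:
        arr = np.empty(shape, dtype=dtype)
        cache[key] = arr
    return arr


class _Conv2D:
    """Stride-1 same-padding convolution as k*k shifted slice matmuls.

    ``y[n,i,j,o] = sum_{ki,kj,c} xpad[n,i+ki,j+kj,c] * W[ki,kj,c,o] + b[o]``
    computed one (ki, kj) shift at a time, so no im2col tensor is ever
    materialised; each term is a (n*h*w, cin) x (cin, cout) BLAS matmul.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = k * k * cin
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(k, k, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._xp: Optional[np.ndarray] = None
        self._cache: dict = {}

    def forward(self, x: np.ndarray, train: bool,
                rng: Optional[np.random.Generator]) -> np.ndarray:
        n, h, w, _ = x.shape
        p = (self.k - 1) // 2
        if _kernels.HAS_NUMBA:
            # channel-first so kernel inner loops run over contiguous rows
            xp = _buf(self._cache, "xp", (n, self.cin, h + 2 * p, w + 2 * p))
            xp[...] = 0.0
            xp[:, :, p:p + h, p:p + w] = x.transpose(0, 3, 1, 2)
            self._xp = xp
            out_cf = _buf(self._cache, "out_cf", (n, self.cout, h, w))
            _kernels.conv_fwd(xp, self.W, self.b, out_cf)
            out = _buf(self._cache, "out", (n, h, w, self.cout))
            out[...] = out_cf.transpose(0, 2, 3, 1)
            return out
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        out = np.zeros((n * h * w, self.cout), dtype=np.float32)
        for ki in range(self.k):
            for kj in range(self.k):
                sl = np.ascontiguousarray(
                    xp[:, ki:ki + h, kj:kj + w, :]).reshape(-1, self.cin)
                out += sl @ self.W[ki, kj]
        return (out + self.b).reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, h, w = dy.shape[:3]
        p = (self.k - 1) // 2
        if _kernels.HAS_NUMBA:
            dy_cf = _buf(self._cache, "dy_cf", (n, self.cout, h, w))
            dy_cf[...] = dy.transpose(0, 3, 1, 2)
            dxp = _buf(self._cache, "dxp", xp.shape)
            dxp[...] = 0.0
            self.grads[0][...] = 0.0
            self.grads[1][...] = 0.0
            _kernels.conv_bwd(xp, self.W, dy_cf, dxp, self.grads[0], self.grads[1])
            dx = _buf(self._cache, "dx", (n, h, w, self.cin))
            dx[...] = dxp[:, :, p:p + h, p:p + w].transpose(0, 2, 3, 1)
            return dx
        dyf = np.ascontiguousarray(dy).reshape(-1, self.cout)
        dxp = np.zeros_like(xp)
        for ki in range(self.k):
            for kj in range(self.k):
                sl = np.ascontiguousarray(
                    xp[:, ki:ki + h, kj:kj + w, :]).reshape(-1, self.cin)
                self.grads[0][ki, kj] = sl.T @ dyf
                dxp[:, ki:ki + h, kj:kj + w, :] += (dyf @ self.W[ki, kj].T
                                                    ).reshape(n, h, w, self.cin)
        self.grads[1][...] = dyf.sum(axis=0)
        return dxp[:, p:p + h, p:p + w, :]

    def describe(self) -> str:
        return f"conv {self.k}x{self.k}, {self.cin}->{self.cout}, stride 1, same padding"


class _LRN:
    """Local response normalisation across channels (window 5, classic constants)."""

    def __init__(self, n: int = 5, alpha: float = 1e-4, beta: float = 0.75,
                 k: float = 2.0):
        self.n, self.alpha, self.beta, self.k = n, alpha, beta, k
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self._x: Optional[np.ndarray] = None
        self._d: Optional[np.ndarray] = None
        self._dpow: Optional[np.ndarray] = None
        self._cache: dict = {}

    def _winsum(self, a: np.ndarray) -> np.ndarray:
        # symmetric sliding sum over the channel axis, window self.n,
        # as shifted-slice adds (channel counts are small)
        r = self.n // 2
        c = a.shape[-1]
        out = a.copy()
        for off in range(1, r + 1):
            out[..., off:] += a[..., :c - off]
            out[..., :c - off] += a[..., off:]
        return out

    def forward(self, x: np.ndarray, train: bool,
                rng: Optional[np.random.Generator]) -> np.ndarray:
        if _kernels.HAS_NUMBA:
            x = np.ascontiguousarray(x)
            y = _buf(self._cache, "y", x.shape)
            d = _buf(self._cache, "d", x.shape)
            dpow = _buf(self._cache, "dpow", x.shape)
            _kernels.lrn_denom(x, self.n, self.alpha, self.k, d)
            np.power(d, -self.beta, out=dpow)
            np.multiply(x, dpow, out=y)
            self._x, self._d, self._dpow = x, d, dpow
            return y
        d = self.k + (self.alpha / self.n) * self._winsum(x * x)
        self._x, self._d = x, d
        self._dpow = None
        return (x * d ** (-self.beta)).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, d = self._x, self._d
        if _kernels.HAS_NUMBA and self._dpow is not None:
            dy = np.ascontiguousarray(dy)
            dx = _buf(self._cache, "dx", x.shape)
            _kernels.lrn_bwd(x, d, self._dpow, dy, self.n, self.alpha,
                             self.beta, dx)
            return dx
        t = dy * x * d ** (-self.beta - 1.0)
        dx = dy * d ** (-self.beta) \
            - (2.0 * self.alpha * self.beta / self.n) * x * self._winsum(t)
        return dx.astype(np.float32)

    def describe(self) -> str:
        return f"LRN n={self.n} alpha={self.alpha} beta={self.beta} k={self.k}"


class _MaxPool:
    """Overlapping max pooling: window > stride, no padding."""

    def __init__(self, window: int = 3, stride: int = 2):
        self.window, self.stride = window, stride
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self._idx: Optional[np.ndarray] = None
        self._in_shape: Optional[tuple] = None
        self._cache: dict = {}

    @staticmethod
    def out_size(n: int, window: int, stride: int) -> int:
        if n < window:
            raise ValueError(f"spatial size {n} underflows pool window {window}")
        return (n - window) // stride + 1

    def forward(self, x: np.ndarray, train: bool,
                rng: Optional[np.random.Generator]) -> np.ndarray:
        n, h, w, c = x.shape
        ho = self.out_size(h, self.window, self.stride)
        wo = self.out_size(w, self.window, self.stride)
        self._in_shape = x.shape
        s, k = self.stride, self.window
        best = _buf(self._cache, "best", (n, ho, wo, c))
        idx = _buf(self._cache, "idx", (n, ho, wo, c), dtype=np.int8)
        if _kernels.HAS_NUMBA:
            _kernels.pool_fwd(np.ascontiguousarray(x), k, s, best, idx)
            self._idx = idx
            return best
        better = _buf(self._cache, "better", (n, ho, wo, c), dtype=bool)
        best[...] = -np.inf
        idx[...] = 0
        for p in range(k * k):  # running max over the window offsets
            ki, kj = divmod(p, k)
            sl = x[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :]
            np.greater(sl, best, out=better)
            np.copyto(best, sl, where=better)
            np.copyto(idx, np.int8(p), where=better)
        self._idx = idx
        return best

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, ho, wo, c = dy.shape
        dx = _buf(self._cache, "dx", self._in_shape)
        s, k = self.stride, self.window
        if _kernels.HAS_NUMBA:
            _kernels.pool_bwd(np.ascontiguousarray(dy), self._idx, k, s, dx)
            return dx
        dx[...] = 0.0
        contrib = _buf(self._cache, "contrib", dy.shape)
        for p in range(k * k):
            ki, kj = divmod(p, k)
            contrib[...] = 0.0
            np.copyto(contrib, dy, where=self._idx == p)
            dx[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :] += contrib
        return dx

    def describe(self) -> str:
        return f"overlapping max-pool {self.window}x{self.window}, stride {self.stride}"


class _Flatten:
    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self._shape: Optional[tuple] = None

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def describe(self) -> str:
        return "flatten"


class _Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator,
                 relu: bool = True):
        self.nin, self.nout, self.relu = nin, nout, relu
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin),
                            size=(nin, nout)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._x: Optional[np.ndarray] = None
        self._pre: Optional[np.ndarray] = None

    def forward(self, x, train, rng):
        self._x = x
        y = x @ self.W + self.b
        if self.relu:
            self._pre = y
            y = np.maximum(y, 0.0)
        return y

    def backward(self, dy):
        if self.relu:
            dy = dy * (self._pre > 0)
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T

    def describe(self) -> str:
        act = "ReLU" if self.relu else "linear"
        return f"fully connected {self.nin}->{self.nout} ({act})"


class _ReLU:
    """Rectifier applied in place on the producing layer's output buffer."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self._mask: Optional[np.ndarray] = None
        self._cache: dict = {}

    def forward(self, x, train, rng):
        mask = _buf(self._cache, "mask", x.shape, dtype=bool)
        np.greater(x, 0, out=mask)
        self._mask = mask
        np.maximum(x, 0.0, out=x)
        return x

    def backward(self, dy):
        np.multiply(dy, self._mask, out=dy)
        return dy

    def describe(self) -> str:
        return "ReLU"


class _Dropout:
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float):
        self.p = p
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self._mask: Optional[np.ndarray] = None

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask

    def describe(self) -> str:
        return f"dropout p={self.p}"


# ---------------------------------------------------------------------------
# model


class Model:
    """Layer stack with softmax cross-entropy head and Adam updates."""

    def __init__(self, config: NetConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        h, w, cin = config.input_shape
        layers: list = []
        self.conv_layers = 0
        self.pool_layers = 0
        self.fc_layers = 0
        for i, (k, cout) in enumerate(zip(config.conv_kernels,
                                          config.conv_channels), start=1):
            layers.append(_Conv2D(cin, cout, k, rng))
            layers.append(_ReLU())
            self.conv_layers += 1
            if config.lrn and i <= 2:
                layers.append(_LRN())
            if i in config.pool_layers:
                layers.append(_MaxPool(config.pool_window, config.pool_stride))
                h = _MaxPool.out_size(h, config.pool_window, config.pool_stride)
                w = _MaxPool.out_size(w, config.pool_window, config.pool_stride)
                self.pool_layers += 1
            cin = cout
        layers.append(_Flatten())
        nin = h * w * cin
        for size in config.fc_sizes:
            layers.append(_Dense(nin, size, rng, relu=True))
            layers.append(_Dropout(config.dropout))
            self.fc_layers += 1
            nin = size
        layers.append(_Dense(nin, config.n_classes, rng, relu=False))
        self.fc_layers += 1
        self.layers = layers
        self.final_spatial = (h, w)

    # -- forward / backward

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def count_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def describe(self) -> dict:
        return {
            "layers": [layer.describe() for layer in self.layers],
            "conv_layers": self.conv_layers,
            "pool_layers": self.pool_layers,
            "fc_layers": self.fc_layers,
            "final_spatial": self.final_spatial,
            "total_params": self.count_params(),
        }

    # -- inference

    @staticmethod
    def _prep(x: np.ndarray) -> np.ndarray:
        return x.astype(np.float32) / 255.0 - 0.5

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        x = np.asarray(x)
        if len(x) == 0:
            return np.zeros((0, self.config.n_classes), dtype=np.float32)
        fbuf = np.empty((min(batch_size, len(x)),) + x.shape[1:], dtype=np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            nb = min(batch_size, len(x) - i)
            xb = fbuf[:nb]
            xb[...] = x[i:i + nb]
            xb *= 1.0 / 255.0
            xb -= 0.5
            logits = self.forward(xb, train=False)
            out.append(_softmax(logits))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        # argmax breaks ties toward the lowest class index
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- persistence

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez(str(path), config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        data = np.load(str(path), allow_pickle=False)
        raw = json.loads(str(data["config"]))
        for key in ("input_shape", "conv_kernels", "conv_channels",
                    "pool_layers", "fc_sizes"):
            raw[key] = tuple(raw[key])
        model = cls(NetConfig(**raw), seed=0)
        for i, p in enumerate(model.params):
            p[...] = data[f"p{i}"]
        return model


def build_model(config: Optional[NetConfig] = None, seed: int = 0) -> Model:
    """Instantiate the improved AlexNet; raises on spatial underflow."""
    return Model(config or NetConfig(), seed=seed)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    n = len(y)
    probs = _softmax(logits)
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self._tmp = {p.shape: np.empty_like(p) for p in params}

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            tmp = self._tmp[p.shape]
            m *= self.b1
            np.multiply(g, 1.0 - self.b1, out=tmp)
            m += tmp
            v *= self.b2
            np.multiply(g, g, out=tmp)
            tmp *= 1.0 - self.b2
            v += tmp
            np.divide(v, b2t, out=tmp)
            np.sqrt(tmp, out=tmp)
            tmp += self.eps
            np.divide(m, tmp, out=tmp)
            tmp *= self.lr / b1t
            p -= tmp


def _eval_loss_acc(model: Model, x: np.ndarray, y: np.ndarray,
                   batch_size: int = 16,
                   fbuf: Optional[np.ndarray] = None) -> tuple[float, float]:
    losses, correct = [], 0
    if fbuf is None or fbuf.shape[0] < batch_size or fbuf.shape[1:] != x.shape[1:]:
        fbuf = np.empty((batch_size,) + x.shape[1:], dtype=np.float32)
    for i in range(0, len(x), batch_size):
        nb = min(batch_size, len(x) - i)
        xb = fbuf[:nb]
        xb[...] = x[i:i + nb]
        xb *= 1.0 / 255.0
        xb -= 0.5
        logits = model.forward(xb, train=False)
        loss, _ = _cross_entropy(logits, y[i:i + nb])
        losses.append(loss * nb)
        correct += int((logits.argmax(axis=1) == y[i:i + nb]).sum())
    return float(np.sum(losses) / len(y)), correct / len(y)


def train(model: Model, train_data: tuple[np.ndarray, np.ndarray],
          test_data: tuple[np.ndarray, np.ndarray],
          config: Optional[TrainConfig] = None,
          verbose: bool = False) -> TrainingHistory:
    """Adam / cross-entropy training with per-epoch test loss and accuracy.

    ``train_data`` and ``test_data`` are (X, y) with X uint8 crops
    (n, 255, 255, 3) and y integer stage labels. Deterministic for a fixed
    ``config.seed`` (seeded shuffling and dropout masks).
    """
    config = config or TrainConfig()
    config.validate()
    x_tr, y_tr = train_data
    x_te, y_te = test_data
    if len(x_tr) == 0 or len(x_te) == 0:
        raise ValueError("empty train or test split")
    y_tr = np.asarray(y_tr, dtype=np.int64)
    y_te = np.asarray(y_te, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    history = TrainingHistory()
    x_tr = np.asarray(x_tr)
    fbuf = np.empty((config.batch_size,) + x_tr.shape[1:], dtype=np.float32)
    ebuf = np.empty((16,) + x_tr.shape[1:], dtype=np.float32)
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = fbuf[:len(idx)]
            xb[...] = x_tr[idx]
            xb *= 1.0 / 255.0
            xb -= 0.5
            logits = model.forward(xb, train=True, rng=rng)
            loss, dlogits = _cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}, batch {i // config.batch_size}")
            model.backward(dlogits)
            opt.step(model.grads)
            epoch_losses.append(loss * len(idx))
        test_loss, test_acc = _eval_loss_acc(model, x_te, y_te, fbuf=ebuf)
        history.loss.append(test_loss)
        history.accuracy.append(test_acc)
        history.train_loss.append(float(np.sum(epoch_losses) / len(order)))
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}: "
                  f"train_loss={history.train_loss[-1]:.4f} "
                  f"test_loss={test_loss:.4f} test_acc={test_acc:.4f}")
    return history


def evaluate(model: Model, x: np.ndarray, y: np.ndarray,
             n_classes: int = 3) -> EvalResult:
    """Accuracy A = N_C / N_T, per-class accuracies and the confusion matrix."""
    y = np.asarray(y, dtype=np.int64)
    if len(y) == 0:
        raise ValueError("empty evaluation split")
    pred = model.predict(np.asarray(x))
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    for t, p in zip(y, pred):
        confusion[t, p] += 1
    n_correct = int(np.trace(confusion))
    per_class = tuple(
        float(confusion[c, c] / confusion[c].sum()) if confusion[c].sum() else float("nan")
        for c in range(n_classes))
    return EvalResult(accuracy=n_correct / len(y), n_correct=n_correct,
                      n_total=len(y), per_class_accuracy=per_class,
                      confusion=confusion)


def classify_crops(model: Model, crops: Sequence) -> np.ndarray:
    """Predict the stage label (0/1/2) for each 255x255x3 crop."""
    from .crops import SeedlingCrop, CROP_SIZE
    arrays = [c.pixels if isinstance(c, SeedlingCrop) else np.asarray(c)
              for c in crops]
    for a in arrays:
        if a.shape != (CROP_SIZE, CROP_SIZE, 3):
            raise ValueError(f"crop must be {CROP_SIZE}x{CROP_SIZE}x3, got {a.shape}")
    if not arrays:
        return np.empty(0, dtype=np.int64)
    return model.predict(np.stack(arrays))
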