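"""Minimal convolutional network for binary pattern classification.

A small, self-contained CNN implemented on numpy: valid 3x3 convolutions via
im2col + BLAS matmul, max-pooling, one dense hidden layer with dropout, and a
single logistic output unit trained with binary cross-entropy and RMSprop.
ReLU activation everywhere except the output.  Everything is float32 and
seeded, so training is bit-reproducible on CPU.

This is deliberately not a general deep-learning framework: the screening
task is a binary decision on 150x150 single-channel images, and the layer
menu covers exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physics import InvalidArgumentError


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training protocol.

    input_pool : fixed (parameter-free) average-pool factor applied to the
        input before the conv stack; 1 disables it.  The default 2 halves the
        spatial size, which costs nothing on spot/ring-scale features and
        makes CPU training of the default stack fast.
    conv_filters : output channels of each 3x3 conv block; each block is
        conv -> ReLU -> max-pool(pool).
    pool : max-pool window per block.
    dense : width of the hidden dense layer.
    dropout : dropout rate on the hidden dense layer during training (0.15).
    batch_size / epochs / lr / rho : RMSprop training protocol
        (batches of 75 images, 20 epochs).
    """

    input_shape: tuple[int, int] = (150, 150)
    input_pool: int = 2
    conv_filters: tuple[int, ...] = (8, 16)
    kernel: int = 3
    pool: int = 4
    dense: int = 48
    dropout: float = 0.15
    batch_size: int = 75
    epochs: int = 20
    lr: float = 1e-3
    rho: float = 0.9
    eps: float = 1e-8


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N * H' * W', C * k * k) patch matrix, valid windows."""
    n, c, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # (N, C, H', W', k, k) -> (N, H', W', C, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols)


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        ho, wo = h - self.k + 1, w - self.k + 1
        self._cols = _im2col(x, self.k)
        out = self._cols @ self.w + self.b
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c_out, ho, wo = dout.shape
        d2 = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.dw = self._cols.T @ d2
        self.db = d2.sum(axis=0)
        dcols = d2 @ self.w.T
        k = self.k
        dcols = dcols.reshape(n, ho, wo, self.c_in, k, k)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + ho, j:j + wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self.grads = [self.dw, self.db]
        return dx


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _AvgPool:
    """Fixed average pooling; used as a parameter-free input downsampler."""

    params: list = []

    def __init__(self, p: int):
        self.p = p

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.p
        hp, wp = h // p, w // p
        self._in_shape = x.shape
        return (x[:, :, :hp * p, :wp * p]
                .reshape(n, c, hp, p, wp, p).mean(axis=(3, 5)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, hp, wp = dout.shape
        p = self.p
        dx = np.zeros(self._in_shape, dtype=np.float32)
        spread = np.broadcast_to(
            dout[:, :, :, None, :, None] / (p * p),
            (n, c, hp, p, wp, p),
        ).reshape(n, c, hp * p, wp * p)
        dx[:, :, :hp * p, :wp * p] = spread
        return dx


class _MaxPool:
    params: list = []

    def __init__(self, p: int):
        self.p = p

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.p
        hp, wp = h // p, w // p
        self._in_shape = x.shape
        flat = (x[:, :, :hp * p, :wp * p]
                .reshape(n, c, hp, p, wp, p)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, hp, wp, p * p))
        # first-max argmax: deterministic tie-break toward the earlier pixel
        self._idx = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, hp, wp = dout.shape
        p = self.p
        dflat = np.zeros((n, c, hp, wp, p * p), dtype=np.float32)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, :hp * p, :wp * p] = (
            dflat.reshape(n, c, hp, wp, p, p)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, hp * p, wp * p))
        return dx


class _Flatten:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self.grads = [self.dw, self.db]
        return dout @ self.w.T


class _Dropout:
    params: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class BinaryCnn:
    """Conv stack + dense head + logistic output, trained with RMSprop/BCE."""

    def __init__(self, config: CnnConfig = CnnConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        h, w = config.input_shape
        layers: list = []
        c_in = 1
        if config.input_pool > 1:
            layers.append(_AvgPool(config.input_pool))
            h //= config.input_pool
            w //= config.input_pool
        for c_out in config.conv_filters:
            layers.append(_Conv(c_in, c_out, config.kernel, rng))
            layers.append(_ReLU())
            layers.append(_MaxPool(config.pool))
            h = (h - config.kernel + 1) // config.pool
            w = (w - config.kernel + 1) // config.pool
            c_in = c_out
        if h < 1 or w < 1:
            raise InvalidArgumentError("input too small for the conv stack")
        layers.append(_Flatten())
        layers.append(_Dense(h * w * c_in, config.dense, rng))
        layers.append(_ReLU())
        layers.append(_Dropout(config.dropout, self._dropout_rng))
        layers.append(_Dense(config.dense, 1, rng))
        self.layers = layers
        self._cache = [
            [np.zeros_like(p) for p in layer.params] for layer in layers
        ]
        self.history: dict[str, list[float]] = {
            "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
        }

    # -- inference ---------------------------------------------------------
    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            if isinstance(layer, _Dropout):
                layer.training = training
            x = layer.forward(x)
        return x  # logits, shape (N, 1)

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Logistic scores in (0, 1) for (N, H, W) or (H, W) input."""
        x = self._prepare(images)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(_sigmoid(self._forward(x[i:i + batch_size], training=False)))
        return np.concatenate(out).ravel()

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != self.config.input_shape:
            raise InvalidArgumentError(
                f"expected images of shape {self.config.input_shape}, got {x.shape}"
            )
        return x[:, None, :, :]

    # -- training ----------------------------------------------------------
    def fit(self, images: np.ndarray, labels: np.ndarray,
            val_images: np.ndarray | None = None,
            val_labels: np.ndarray | None = None,
            seed: int = 0, verbose: bool = False) -> "BinaryCnn":
        x = self._prepare(images)
        y = np.asarray(labels, dtype=np.float32).ravel()
        if set(np.unique(y)) - {0.0, 1.0}:
            raise InvalidArgumentError("labels must be 0/1")
        if len(np.unique(y)) < 2:
            raise InvalidArgumentError("training set must contain both classes")
        cfg = self.config
        shuffle_rng = np.random.default_rng(seed)
        n = x.shape[0]
        for epoch in range(cfg.epochs):
            order = shuffle_rng.permutation(n)
            losses = []
            correct = 0
            for i in range(0, n, cfg.batch_size):
                idx = order[i:i + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                logits = self._forward(xb, training=True).ravel()
                p = _sigmoid(logits)
                eps = 1e-7
                losses.append(float(-np.mean(
                    yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))) * len(idx))
                correct += int(((p > 0.5) == (yb > 0.5)).sum())
                dlogits = ((p - yb) / len(idx)).astype(np.float32)[:, None]
                self._backward(dlogits)
                self._rmsprop_step()
            self.history["loss"].append(sum(losses) / n)
            self.history["accuracy"].append(correct / n)
            if val_images is not None and val_labels is not None:
                vp = self.predict_proba(val_images)
                vy = np.asarray(val_labels, dtype=np.float32).ravel()
                eps = 1e-7
                self.history["val_loss"].append(float(-np.mean(
                    vy * np.log(vp + eps) + (1 - vy) * np.log(1 - vp + eps))))
                self.history["val_accuracy"].append(
                    float(((vp > 0.5) == (vy > 0.5)).mean()))
            if verbose:
                msg = (f"epoch {epoch + 1}/{cfg.epochs} "
                       f"loss={self.history['loss'][-1]:.4f} "
                       f"acc={self.history['accuracy'][-1]:.4f}")
                if self.history["val_accuracy"]:
                    msg += f" val_acc={self.history['val_accuracy'][-1]:.4f}"
                print(msg)
        return self

    def _backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def _rmsprop_step(self) -> None:
        cfg = self.config
        for layer, caches in zip(self.layers, self._cache):
            if not layer.params:
                continue
            for p, g, c in zip(layer.params, layer.grads, caches):
                c *= cfg.rho
                c += (1.0 - cfg.rho) * g * g
                p -= cfg.lr * g / (np.sqrt(c) + cfg.eps)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint weights + config to an .npz file."""
        arrays = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                arrays[f"param_{i}_{j}"] = p
        cfg = self.config
        meta = np.array([
            cfg.input_shape[0], cfg.input_shape[1], cfg.kernel, cfg.pool,
            cfg.dense, cfg.batch_size, cfg.epochs, cfg.input_pool,
        ], dtype=np.int64)
        arrays["meta"] = meta
        arrays["conv_filters"] = np.array(cfg.conv_filters, dtype=np.int64)
        arrays["floats"] = np.array([cfg.dropout, cfg.lr, cfg.rho, cfg.eps])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "BinaryCnn":
        data = np.load(path)
        meta = data["meta"]
        cfg = CnnConfig(
            input_shape=(int(meta[0]), int(meta[1])),
            conv_filters=tuple(int(v) for v in data["conv_filters"]),
            kernel=int(meta[2]), pool=int(meta[3]), dense=int(meta[4]),
            batch_size=int(meta[5]), epochs=int(meta[6]), input_pool=int(meta[7]),
            dropout=float(data["floats"][0]), lr=float(data["floats"][1]),
            rho=float(data["floats"][2]), eps=float(data["floats"][3]),
        )
        model = cls(cfg, seed=0)
        for i, layer in enumerate(model.layers):
            for j in range(len(layer.params)):
                layer.params[j][...] = data[f"param_{i}_{j}"]
        return model
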