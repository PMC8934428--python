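"""Minimal NumPy neural-network engine for the two small detector networks.

Implements exactly the layer set the CNN and LSTM architectures need —
valid-padding 1-D convolution over multichannel windows, batch normalization,
ReLU, max pooling, dropout, dense, LSTM, time-distributed dense and global
average pooling — plus Adam, class-weighted binary cross-entropy and
early stopping.  Sizes are tiny (a few thousand parameters), so a vectorized
NumPy implementation trains them in seconds to minutes on one CPU.

Conventions: CNN tensors are (batch, channels, time); recurrent tensors are
(batch, time, features).  All math in float32.  Every source of randomness
(init, shuffling, dropout) comes from an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "Dense",
    "Conv1d",
    "BatchNorm",
    "ReLU",
    "MaxPool1d",
    "Dropout",
    "Flatten",
    "LSTM",
    "TimeDistributedDense",
    "GlobalAveragePooling",
    "Sequential",
    "Adam",
    "fit",
    "sigmoid",
]

F32 = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    """Base layer; stateless layers only override forward/backward."""

    def params(self) -> list[str]:
        return []

    def buffers(self) -> list[str]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        return []

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - default
        pass

    def n_params(self) -> int:
        return int(sum(getattr(self, p).size for p in self.params()))

    def forward(self, x, train: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int):
        self.n_in, self.n_out = n_in, n_out
        self.W = np.zeros((n_in, n_out), F32)
        self.b = np.zeros(n_out, F32)

    def params(self):
        return ["W", "b"]

    def init(self, rng):
        self.W = _glorot(rng, (self.n_in, self.n_out), self.n_in, self.n_out)
        self.b = np.zeros(self.n_out, F32)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


class Conv1d(Layer):
    """Valid-padding convolution over (B, C_in, T) -> (B, C_out, T-k+1)."""

    def __init__(self, c_in: int, c_out: int, kernel: int):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.W = np.zeros((c_out, c_in * kernel), F32)
        self.b = np.zeros(c_out, F32)

    def params(self):
        return ["W", "b"]

    def init(self, rng):
        fan_in = self.c_in * self.kernel
        self.W = _glorot(rng, (self.c_out, fan_in), fan_in, self.c_out)
        self.b = np.zeros(self.c_out, F32)

    def forward(self, x, train, rng):
        k = self.kernel
        if x.shape[2] < k:
            raise ValueError(
                f"conv kernel {k} longer than input length {x.shape[2]} "
                f"(layer {self.c_in}->{self.c_out})"
            )
        # (B, C_in, T_out, k) -> (B, T_out, C_in * k)
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            x.shape[0], -1, self.c_in * k
        )
        self._col, self._in_shape = col, x.shape
        flat = col.reshape(-1, self.c_in * k) @ self.W.T + self.b
        out = flat.reshape(x.shape[0], -1, self.c_out)  # (B, T_out, C_out)
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, grad):
        g = grad.transpose(0, 2, 1)  # (B, T_out, C_out)
        b_, t_out, _ = g.shape
        gf = g.reshape(-1, self.c_out)
        self.dW = gf.T @ self._col.reshape(-1, self.c_in * self.kernel)
        self.db = gf.sum(axis=0)
        dcol = (gf @ self.W).reshape(b_, t_out, self.c_in, self.kernel)
        dx = np.zeros(self._in_shape, F32)
        for j in range(self.kernel):
            dx[:, :, j : j + t_out] += dcol[:, :, :, j].transpose(0, 2, 1)
        return dx


class BatchNorm(Layer):
    """Per-feature-map normalization over batch and time, Keras defaults."""

    def __init__(self, c: int, momentum: float = 0.99, eps: float = 1e-3):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = np.ones(c, F32)
        self.beta = np.zeros(c, F32)
        self.running_mean = np.zeros(c, F32)
        self.running_var = np.ones(c, F32)

    def params(self):
        return ["gamma", "beta"]

    def buffers(self):
        return ["running_mean", "running_var"]

    def n_params(self) -> int:
        # scale, shift, running mean and running variance per map, as reported
        # in framework architecture summaries
        return 4 * self.c

    def forward(self, x, train, rng):
        axes = (0, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._xhat, self._inv, self._train_n = xhat, inv, x.shape[0] * x.shape[2]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, grad):
        n = self._train_n
        xhat, inv = self._xhat, self._inv
        self.dgamma = (grad * xhat).sum(axis=(0, 2))
        self.dbeta = grad.sum(axis=(0, 2))
        g = grad * self.gamma[None, :, None]
        return (
            inv[None, :, None]
            * (
                g
                - g.mean(axis=(0, 2))[None, :, None]
                - xhat * (g * xhat).mean(axis=(0, 2))[None, :, None]
            )
        ).astype(F32)


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0).astype(F32)


class MaxPool1d(Layer):
    def __init__(self, k: int):
        self.k = k

    def forward(self, x, train, rng):
        b, c, t = x.shape
        t_out = t // self.k
        xr = x[:, :, : t_out * self.k].reshape(b, c, t_out, self.k)
        self._arg = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad):
        b, c, t_out = grad.shape
        dx = np.zeros((b, c, t_out, self.k), F32)
        bi, ci, ti = np.ogrid[:b, :c, :t_out]
        dx[bi, ci, ti, self._arg] = grad
        out = np.zeros(self._in_shape, F32)
        out[:, :, : t_out * self.k] = dx.reshape(b, c, t_out * self.k)
        return out


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class LSTM(Layer):
    """Single LSTM layer over (B, T, C) -> (B, T, H); gate order [i, f, g, o].

    Standard formulation: i, f, o use logistic gates, g and the cell output
    use tanh.  Forget-gate bias initialized to 1.  Parameter count is
    4 * ((C + H) * H + H).
    """

    def __init__(self, n_in: int, n_hidden: int):
        self.n_in, self.h = n_in, n_hidden
        self.Wx = np.zeros((n_in, 4 * n_hidden), F32)
        self.Wh = np.zeros((n_hidden, 4 * n_hidden), F32)
        self.b = np.zeros(4 * n_hidden, F32)

    def params(self):
        return ["Wx", "Wh", "b"]

    def init(self, rng):
        h = self.h
        self.Wx = _glorot(rng, (self.n_in, 4 * h), self.n_in, h)
        self.Wh = _glorot(rng, (h, 4 * h), h, h)
        self.b = np.zeros(4 * h, F32)
        self.b[h : 2 * h] = 1.0  # forget gate bias

    def forward(self, x, train, rng):
        b_, t_, _ = x.shape
        h = self.h
        hs = np.zeros((t_, b_, h), F32)
        cache = []
        h_prev = np.zeros((b_, h), F32)
        c_prev = np.zeros((b_, h), F32)
        xw = x @ self.Wx  # (B, T, 4H), hoisted out of the loop
        for t in range(t_):
            z = xw[:, t, :] + h_prev @ self.Wh + self.b
            i = sigmoid(z[:, :h])
            f = sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = sigmoid(z[:, 3 * h :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_new = o * tc
            cache.append((h_prev, c_prev, i, f, g, o, tc))
            hs[t] = h_new
            h_prev, c_prev = h_new, c
        self._x, self._cache = x, cache
        return hs.transpose(1, 0, 2)

    def backward(self, grad):
        x, cache = self._x, self._cache
        b_, t_, _ = x.shape
        h = self.h
        g_out = grad.transpose(1, 0, 2)  # (T, B, H)
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((b_, h), F32)
        dc_next = np.zeros((b_, h), F32)
        for t in range(t_ - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = g_out[t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            ).astype(F32)
            dWx += x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        self.dWx, self.dWh, self.db = dWx, dWh, db
        return dx


class TimeDistributedDense(Layer):
    """Linear dense applied independently at every time step: (B, T, n_in)."""

    def __init__(self, n_in: int, n_out: int):
        self.n_in, self.n_out = n_in, n_out
        self.W = np.zeros((n_in, n_out), F32)
        self.b = np.zeros(n_out, F32)

    def params(self):
        return ["W", "b"]

    def init(self, rng):
        self.W = _glorot(rng, (self.n_in, self.n_out), self.n_in, self.n_out)
        self.b = np.zeros(self.n_out, F32)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = np.einsum("bti,bto->io", self._x, grad).astype(F32)
        self.db = grad.sum(axis=(0, 1))
        return grad @ self.W.T


class GlobalAveragePooling(Layer):
    """Mean over the time axis of (B, T, H)."""

    def forward(self, x, train, rng):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._t, axis=1) / self._t


class Sequential:
    """Layer chain ending in a single logit; sigmoid applied at predict time."""

    def __init__(self, layers: list[Layer], rng: np.random.Generator | None = None):
        self.layers = layers
        if rng is not None:
            self.initialize(rng)

    def initialize(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init(rng)

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x, batch_size: int = 1024) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            z = self.forward(np.asarray(x[i : i + batch_size], F32), train=False)
            out.append(sigmoid(z[:, 0]))
        return np.concatenate(out) if out else np.empty(0)

    def get_weights(self) -> list[np.ndarray]:
        return [
            getattr(l, p).copy()
            for l in self.layers
            for p in l.params() + l.buffers()
        ]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for p in layer.params() + layer.buffers():
                setattr(layer, p, next(it).copy().astype(F32))

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def clone(self) -> "Sequential":
        return copy.deepcopy(self)


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(l, p)) for l in model.layers for p in l.params()]
        self.v = [np.zeros_like(x) for x in self.m]

    def step(self) -> None:
        self.t += 1
        idx = 0
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for layer in self.model.layers:
            for p in layer.params():
                g = getattr(layer, "d" + p)
                self.m[idx] = self.beta1 * self.m[idx] + (1 - self.beta1) * g
                self.v[idx] = self.beta2 * self.v[idx] + (1 - self.beta2) * g * g
                mhat = self.m[idx] / b1t
                vhat = self.v[idx] / b2t
                val = getattr(layer, p) - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                setattr(layer, p, val.astype(F32))
                idx += 1


def _bce_with_logits(z: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted binary cross-entropy on logits; returns (loss, dL/dz)."""
    z = z[:, 0]
    loss = np.logaddexp(0.0, z) - y * z  # softplus(z) - y z
    wmean = w / len(z)
    grad = (wmean * (sigmoid(z) - y)).astype(F32)[:, None]
    return float((wmean * loss).sum()), grad


def evaluate_loss(model: Sequential, x, y, w=None, batch_size: int = 1024) -> float:
    w = np.ones(len(y), F32) if w is None else w
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        z = model.forward(np.asarray(x[i : i + batch_size], F32), train=False)[:, 0]
        yi, wi = y[i : i + batch_size], w[i : i + batch_size]
        total += float((wi * (np.logaddexp(0.0, z) - yi * z)).sum())
        n += len(yi)
    return total / max(n, 1)


def fit(
    model: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    lr: float,
    rng: np.random.Generator,
    sample_weight: np.ndarray | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    patience: int | None = None,
    shuffle: bool = True,
) -> dict:
    """Adam / class-weighted BCE training loop with optional early stopping.

    Early stopping (when ``patience`` is given) monitors validation loss,
    stops once ``patience`` epochs pass without improvement, and restores the
    best weights.  Returns a history dict with per-epoch train/validation loss
    and the epoch at which training stopped.
    """
    if patience is not None and validation is None:
        raise ValueError("early stopping requires validation data")
    x = np.asarray(x, F32)
    y = np.asarray(y, F32)
    w = np.ones(len(y), F32) if sample_weight is None else np.asarray(sample_weight, F32)
    opt = Adam(model, lr=lr)
    history: dict = {"loss": [], "val_loss": [], "stopped_epoch": None, "best_epoch": None}
    best_val, best_weights, best_epoch = np.inf, None, -1

    for epoch in range(epochs):
        order = rng.permutation(len(y)) if shuffle else np.arange(len(y))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            z = model.forward(x[idx], train=True, rng=rng)
            loss, grad = _bce_with_logits(z, y[idx], w[idx])
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history["loss"].append(epoch_loss / max(n_batches, 1))

        if validation is not None:
            vloss = evaluate_loss(model, validation[0], validation[1])
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val, best_epoch = vloss, epoch
                best_weights = model.get_weights()
            if patience is not None and epoch - best_epoch >= patience:
                history["stopped_epoch"] = epoch
                break

    if best_weights is not None:
        model.set_weights(best_weights)
    history["best_epoch"] = best_epoch if best_epoch >= 0 else None
    if history["stopped_epoch"] is None:
        history["stopped_epoch"] = len(history["loss"]) - 1
    return history
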