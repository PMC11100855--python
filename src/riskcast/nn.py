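"""A small numpy CNN with hand-written backpropagation.

Implements exactly the layer stack used for next-day event prediction:

    conv 3x3 / 32, ReLU -> batch norm -> max pool 2x2
    conv 2x2 / 64, ReLU -> batch norm -> max pool 2x2
    flatten -> dense 64, ReLU -> dropout 0.5 -> dense 1 -> sigmoid

Conventions: channels-last tensors ``(N, H, W, C)``; "same" convolution
padding (a 2x2 kernel pads one row/column at the bottom/right); pooling uses
floor division with stride 2; batch norm keeps exponential running statistics
for inference; dropout is inverted (scaled at train time, identity at eval).
Training minimizes binary cross-entropy with Adam.

Everything is float64 and seeded, so training is reproducible on a given
platform, and the first layer's post-ReLU feature maps are exposed together
with exact gradients of the output logit with respect to them — the
quantities class-activation mapping needs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCNN", "TrainingDivergedError", "sigmoid", "bce_loss"]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, computed from logits for stability."""
    # log(1 + e^-|z|) + max(z,0) - z*y
    return float(np.mean(np.log1p(np.exp(-np.abs(logits))) + np.maximum(logits, 0) - logits * y))


def _same_pad(k: int) -> tuple[int, int]:
    """'Same' padding (begin, end) for kernel size k, stride 1: total k-1,
    the extra row/column goes at the end for even k."""
    return ((k - 1) // 2, k - 1 - (k - 1) // 2)


# ---------------------------------------------------------------------------
# Layers.  Each layer caches what its backward pass needs on forward().


class Conv2D:
    def __init__(self, kh: int, kw: int, c_in: int, c_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (kh * kw * c_in + kh * kw * c_out))  # Glorot uniform
        self.w = rng.uniform(-limit, limit, size=(kh, kw, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        kh, kw = self.w.shape[:2]
        (pt, pb), (pl, pr) = _same_pad(kh), _same_pad(kw)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        # patches: (N, H, W, C_in, kh, kw)
        patches = sliding_window_view(xp, (kh, kw), axis=(1, 2))
        out = np.einsum("nhwcuv,uvco->nhwo", patches, self.w, optimize=True) + self.b
        self._cache = (patches, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        patches, x_shape = self._cache
        kh, kw = self.w.shape[:2]
        (pt, _), (pl, _) = _same_pad(kh), _same_pad(kw)
        self.dw += np.einsum("nhwcuv,nhwo->uvco", patches, dout, optimize=True)
        self.db += dout.sum(axis=(0, 1, 2))
        n, h, w, _ = x_shape
        dxp = np.zeros((n, h + kh - 1, w + kw - 1, self.w.shape[2]))
        for u in range(kh):
            for v in range(kw):
                dxp[:, u : u + h, v : v + w, :] += np.einsum(
                    "nhwo,co->nhwc", dout, self.w[u, v], optimize=True
                )
        return dxp[:, pt : pt + h, pl : pl + w, :]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm:
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self._cache = None
        self._eval_mode = False

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.shape)
        self._eval_mode = not training
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape = self._cache
        self.dgamma += (dout * xhat).sum(axis=axes)
        self.dbeta += dout.sum(axis=axes)
        if self._eval_mode:
            # Running statistics are constants at inference: the layer is affine.
            return dout * self.gamma * inv
        m = np.prod([shape[a] for a in axes])
        dxhat = dout * self.gamma
        return (inv / m) * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )


class MaxPool2x2:
    """2x2 max pooling, stride 2, floor division (trailing odd row/column
    dropped).  Ties route the gradient to the first maximal position."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        hh, ww = h // 2, w // 2
        xr = x[:, : hh * 2, : ww * 2, :].reshape(n, hh, 2, ww, 2, c)
        windows = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, hh, ww, c, 4)
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._cache
        hh, ww = h // 2, w // 2
        dwin = np.zeros((n, hh, ww, c, 4))
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, h, w, c))
        dx[:, : hh * 2, : ww * 2, :] = (
            dwin.reshape(n, hh, ww, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, hh * 2, ww * 2, c)
        )
        return dx


class Flatten:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.w.T


class Dropout:
    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params  # list of (value, grad) array pairs
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


# ---------------------------------------------------------------------------


def _pooled_dim(d: int) -> int:
    return d // 2


class SmallCNN:
    """The two-conv-block binary classifier over W x C binary windows."""

    def __init__(
        self,
        input_shape: tuple[int, int],
        conv1_filters: int = 32,
        conv1_kernel: tuple[int, int] = (3, 3),
        conv2_filters: int = 64,
        conv2_kernel: tuple[int, int] = (2, 2),
        dense_units: int = 64,
        dropout_rate: float = 0.5,
        seed: int = 0,
    ):
        h, w = input_shape
        if h < 4 or w < 4:
            raise ValueError(
                f"input spatial dims {input_shape} too small: two 2x2 floor-poolings "
                "require both dims >= 4 so at least one cell survives"
            )
        self.input_shape = (h, w)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        self.conv1 = Conv2D(*conv1_kernel, 1, conv1_filters, rng)
        self.relu1 = ReLU()
        self.bn1 = BatchNorm(conv1_filters)
        self.pool1 = MaxPool2x2()
        self.conv2 = Conv2D(*conv2_kernel, conv1_filters, conv2_filters, rng)
        self.relu2 = ReLU()
        self.bn2 = BatchNorm(conv2_filters)
        self.pool2 = MaxPool2x2()
        self.flatten = Flatten()
        h2, w2 = _pooled_dim(_pooled_dim(h)), _pooled_dim(_pooled_dim(w))
        self.flat_dim = h2 * w2 * conv2_filters
        self.dense1 = Dense(self.flat_dim, dense_units, rng)
        self.relu3 = ReLU()
        self.dropout = Dropout(dropout_rate)
        self.dense2 = Dense(dense_units, 1, rng)
        self.history: list[float] = []
        self._first_maps = None  # post-ReLU conv1 activations from last forward

    # -- forward / backward -------------------------------------------------

    def _layers(self):
        return [
            self.conv1, self.relu1, self.bn1, self.pool1,
            self.conv2, self.relu2, self.bn2, self.pool2,
            self.flatten, self.dense1, self.relu3, self.dropout, self.dense2,
        ]

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits of shape (N,).  Caches intermediates for backward()."""
        a = self.relu1.forward(self.conv1.forward(x))
        self._first_maps = a
        a = self.pool1.forward(self.bn1.forward(a, training))
        a = self.relu2.forward(self.conv2.forward(a))
        a = self.pool2.forward(self.bn2.forward(a, training))
        a = self.flatten.forward(a)
        a = self.relu3.forward(self.dense1.forward(a))
        a = self.dropout.forward(a, training, rng)
        return self.dense2.forward(a)[:, 0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(logit); returns d(loss)/d(input)."""
        d = self.dense2.backward(dlogit[:, None])
        d = self.dropout.backward(d)
        d = self.dense1.backward(self.relu3.backward(d))
        d = self.flatten.backward(d)
        d = self.bn2.backward(self.pool2.backward(d))
        d = self.conv2.backward(self.relu2.backward(d))
        d = self.bn1.backward(self.pool1.backward(d))
        d = self.conv1.backward(self.relu1.backward(d))
        return d

    # -- training -----------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ) -> list[float]:
        """Adam + binary cross-entropy; records mean loss per epoch."""
        if len(x) == 0:
            raise ValueError("empty training set")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        opt = Adam(self.params(), lr=learning_rate)
        n = len(x)
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                opt.zero_grad()
                logits = self.forward(xb, training=True, rng=rng)
                loss = bce_loss(logits, yb)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at step {opt.t}: {loss!r}"
                    )
                losses.append(loss)
                # d(mean BCE)/d(logit) with sigmoid folded in
                self.backward((sigmoid(logits) - yb) / len(yb))
                opt.step()
            self.history.append(float(np.mean(losses)))
        return self.history

    # -- inference ----------------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(np.asarray(x, dtype=float), training=False))

    # -- first-layer access for class-activation mapping --------------------

    def first_layer_maps(self, x: np.ndarray) -> np.ndarray:
        """Post-ReLU feature maps of the first conv layer, shape (N, H, W, K).
        With 'same' padding these share the input's spatial grid."""
        self.forward(np.asarray(x, dtype=float), training=False)
        return self._first_maps.copy()

    def forward_from_first_maps(self, maps: np.ndarray) -> np.ndarray:
        """Logits recomputed from (possibly perturbed) first-layer maps, in
        inference mode.  Lets finite-difference checks probe d(logit)/d(map)."""
        a = self.pool1.forward(self.bn1.forward(maps, training=False))
        a = self.relu2.forward(self.conv2.forward(a))
        a = self.pool2.forward(self.bn2.forward(a, training=False))
        a = self.flatten.forward(a)
        a = self.relu3.forward(self.dense1.forward(a))
        a = self.dropout.forward(a, training=False, rng=None)
        return self.dense2.forward(a)[:, 0]

    def grad_wrt_input(self, x: np.ndarray) -> np.ndarray:
        """d(logit)/d(input), shape (N, H, W, 1), inference mode."""
        x = np.asarray(x, dtype=float)
        self.forward(x, training=False)
        dx = self.backward(np.ones(len(x)))
        for _, g in self.params():
            g[...] = 0.0
        return dx

    def grad_wrt_first_maps(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(first-layer maps, d(logit)/d(maps)), both (N, H, W, K), inference
        mode.  The gradient is of the positive-class logit (pre-sigmoid
        score), one output per sample."""
        x = np.asarray(x, dtype=float)
        maps = self.first_layer_maps(x)
        d = self.dense2.backward(np.ones((len(x), 1)))
        d = self.dropout.backward(d)
        d = self.dense1.backward(self.relu3.backward(d))
        d = self.flatten.backward(d)
        d = self.bn2.backward(self.pool2.backward(d))
        d = self.conv2.backward(self.relu2.backward(d))
        d = self.bn1.backward(self.pool1.backward(d))
        # zero out the parameter gradients this sweep accumulated
        for _, g in self.params():
            g[...] = 0.0
        return maps, d

    # -- (de)serialization --------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {
            "conv1_w": self.conv1.w, "conv1_b": self.conv1.b,
            "bn1_gamma": self.bn1.gamma, "bn1_beta": self.bn1.beta,
            "bn1_mean": self.bn1.running_mean, "bn1_var": self.bn1.running_var,
            "conv2_w": self.conv2.w, "conv2_b": self.conv2.b,
            "bn2_gamma": self.bn2.gamma, "bn2_beta": self.bn2.beta,
            "bn2_mean": self.bn2.running_mean, "bn2_var": self.bn2.running_var,
            "dense1_w": self.dense1.w, "dense1_b": self.dense1.b,
            "dense2_w": self.dense2.w, "dense2_b": self.dense2.b,
            "history": np.asarray(self.history, dtype=float),
        }

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        self.conv1.w, self.conv1.b = state["conv1_w"], state["conv1_b"]
        self.bn1.gamma, self.bn1.beta = state["bn1_gamma"], state["bn1_beta"]
        self.bn1.running_mean, self.bn1.running_var = state["bn1_mean"], state["bn1_var"]
        self.conv2.w, self.conv2.b = state["conv2_w"], state["conv2_b"]
        self.bn2.gamma, self.bn2.beta = state["bn2_gamma"], state["bn2_beta"]
        self.bn2.running_mean, self.bn2.running_var = state["bn2_mean"], state["bn2_var"]
        self.dense1.w, self.dense1.b = state["dense1_w"], state["dense1_b"]
        self.dense2.w, self.dense2.b = state["dense2_w"], state["dense2_b"]
        self.history = list(np.asarray(state.get("history", []), dtype=float))
        # re-wire gradient buffers to the new shapes
        for layer in (self.conv1, self.conv2, self.dense1, self.dense2):
            layer.dw = np.zeros_like(layer.w)
            layer.db = np.zeros_like(layer.b)
        for bn in (self.bn1, self.bn2):
            bn.dgamma = np.zeros_like(bn.gamma)
            bn.dbeta = np.zeros_like(bn.beta)
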