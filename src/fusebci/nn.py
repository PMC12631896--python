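"""Minimal CPU neural-network core used by the base and fusion networks.

Layers operate on ``(batch, channels, length)`` arrays (convolutional part)
or ``(batch, features)`` (head).  Each layer implements

    forward(x, train) -> (y, cache)
    backward(cache, grad_y) -> grad_x      # accumulates parameter grads

The explicit cache makes multiple forward passes through one network (source
batch and target batch within the same training step) independent, which the
transfer losses require.  All gradients are exact analytic expressions and
are verified against central finite differences in the test suite.

Weight initialization is a uniform fan-in scheme driven by an explicit
``numpy.random.Generator``; there is no global random state anywhere.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1d",
    "DepthwiseConv1d",
    "BatchNorm1d",
    "Sigmoid",
    "AdaptiveAvgPool1d",
    "Crop1d",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base layer: parameter dict + matching gradient dict."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, cache, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def _uniform_fan_in(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d(Layer):
    """1-D convolution (cross-correlation), stride 1, symmetric zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.padding = kernel, padding
        fan_in = in_channels * kernel
        self.params["W"] = _uniform_fan_in(rng, (out_channels, in_channels, kernel), fan_in)
        self.params["b"] = _uniform_fan_in(rng, (out_channels,), fan_in)
        self.zero_grads()

    def out_length(self, L: int) -> int:
        n = L + 2 * self.padding - self.kernel + 1
        if n < 1:
            raise ValueError(f"Conv1d: non-positive output length {n} for input {L}")
        return n

    def forward(self, x, train):
        B, C, L = x.shape
        if C != self.in_channels:
            raise ValueError(f"Conv1d expected {self.in_channels} channels, got {C}")
        Lo = self.out_length(L)
        xp = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        W = self.params["W"]
        y = np.empty((B, self.out_channels, Lo))
        y[:] = self.params["b"][None, :, None]
        for k in range(self.kernel):
            y += np.einsum("oc,bcl->bol", W[:, :, k], xp[:, :, k:k + Lo],
                           optimize=True)
        return y, (xp, Lo)

    def backward(self, cache, gy):
        xp, Lo = cache
        W = self.params["W"]
        gW = self.grads["W"]
        for k in range(self.kernel):
            gW[:, :, k] += np.einsum("bcl,bol->oc", xp[:, :, k:k + Lo], gy,
                                     optimize=True)
        self.grads["b"] += gy.sum(axis=(0, 2))
        gxp = np.zeros_like(xp)
        for k in range(self.kernel):
            gxp[:, :, k:k + Lo] += np.einsum("oc,bol->bcl", W[:, :, k], gy,
                                             optimize=True)
        p = self.padding
        return gxp[:, :, p:xp.shape[2] - p] if p else gxp


class DepthwiseConv1d(Layer):
    """Per-channel temporal convolution (the depthwise half of a separable
    convolution); channel count is preserved."""

    def __init__(self, channels: int, kernel: int, padding: int = 0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels, self.kernel, self.padding = channels, kernel, padding
        self.params["W"] = _uniform_fan_in(rng, (channels, kernel), kernel)
        self.params["b"] = _uniform_fan_in(rng, (channels,), kernel)
        self.zero_grads()

    def out_length(self, L: int) -> int:
        n = L + 2 * self.padding - self.kernel + 1
        if n < 1:
            raise ValueError(f"DepthwiseConv1d: non-positive output length {n}")
        return n

    def forward(self, x, train):
        B, C, L = x.shape
        if C != self.channels:
            raise ValueError(f"DepthwiseConv1d expected {self.channels} channels, got {C}")
        Lo = self.out_length(L)
        xp = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        W = self.params["W"]
        y = np.broadcast_to(self.params["b"][None, :, None], (B, C, Lo)).copy()
        for k in range(self.kernel):
            y += W[None, :, k, None] * xp[:, :, k:k + Lo]
        return y, (xp, Lo)

    def backward(self, cache, gy):
        xp, Lo = cache
        W = self.params["W"]
        for k in range(self.kernel):
            self.grads["W"][:, k] += (xp[:, :, k:k + Lo] * gy).sum(axis=(0, 2))
        self.grads["b"] += gy.sum(axis=(0, 2))
        gxp = np.zeros_like(xp)
        for k in range(self.kernel):
            gxp[:, :, k:k + Lo] += W[None, :, k, None] * gy
        p = self.padding
        return gxp[:, :, p:xp.shape[2] - p] if p else gxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length).

    Batch statistics in training, frozen running statistics at evaluation.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        #: auxiliary train-mode passes (e.g. transfer-loss feature passes on
        #: source-domain batches) can disable this so evaluation statistics
        #: reflect only the data the classifier is trained on
        self.track_running = True
        self.zero_grads()

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            if self.track_running:
                self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
                self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) / std[None, :, None]
        y = self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]
        return y, (xhat, std, train)

    def backward(self, cache, gy):
        xhat, std, train = cache
        self.grads["gamma"] += (gy * xhat).sum(axis=(0, 2))
        self.grads["beta"] += gy.sum(axis=(0, 2))
        g = self.params["gamma"][None, :, None] / std[None, :, None]
        if not train:
            return g * gy
        m = gy.shape[0] * gy.shape[2]
        gy_mean = gy.mean(axis=(0, 2))[None, :, None]
        proj = (gy * xhat).mean(axis=(0, 2))[None, :, None]
        return g * (gy - gy_mean - xhat * proj)


class Sigmoid(Layer):
    def forward(self, x, train):
        y = 1.0 / (1.0 + np.exp(-x))
        return y, y

    def backward(self, cache, gy):
        y = cache
        return gy * y * (1.0 - y)


class AdaptiveAvgPool1d(Layer):
    """Average pooling to an explicit output length.

    Bin ``i`` averages input samples ``[floor(i*L/O), ceil((i+1)*L/O))``.
    With ``O = L // factor`` and ``factor | L`` this is plain non-overlapping
    average pooling by ``factor``; a non-divisible target reproduces printed
    architecture lengths exactly.
    """

    def __init__(self, out_length: int):
        super().__init__()
        if out_length < 1:
            raise ValueError("pooling output length must be >= 1")
        self.out_length = out_length

    def _bins(self, L: int):
        O = self.out_length
        if O > L:
            raise ValueError(f"cannot pool length {L} up to {O}")
        starts = (np.arange(O) * L) // O
        ends = -(-(np.arange(1, O + 1) * L) // O)  # ceil
        return starts, ends

    def forward(self, x, train):
        B, C, L = x.shape
        starts, ends = self._bins(L)
        y = np.empty((B, C, self.out_length))
        for i, (a, b) in enumerate(zip(starts, ends)):
            y[:, :, i] = x[:, :, a:b].mean(axis=2)
        return y, (L, starts, ends)

    def backward(self, cache, gy):
        L, starts, ends = cache
        gx = np.zeros(gy.shape[:2] + (L,))
        for i, (a, b) in enumerate(zip(starts, ends)):
            gx[:, :, a:b] += gy[:, :, i:i + 1] / (b - a)
        return gx


class Crop1d(Layer):
    """Drop the last ``n`` temporal samples (printed-architecture compatibility)."""

    def __init__(self, n: int):
        super().__init__()
        self.n = n

    def forward(self, x, train):
        return x[:, :, : x.shape[2] - self.n], x.shape[2]

    def backward(self, cache, gy):
        L = cache
        gx = np.zeros(gy.shape[:2] + (L,))
        gx[:, :, : L - self.n] = gy
        return gx


class Flatten(Layer):
    def forward(self, x, train):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, cache, gy):
        return gy.reshape(cache)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features, self.out_features = in_features, out_features
        self.params["W"] = _uniform_fan_in(rng, (in_features, out_features), in_features)
        self.params["b"] = _uniform_fan_in(rng, (out_features,), in_features)
        self.zero_grads()

    def forward(self, x, train):
        if x.shape[1] != self.in_features:
            raise ValueError(
                f"Linear expected {self.in_features} features, got {x.shape[1]}"
            )
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, cache, gy):
        x = cache
        self.grads["W"] += x.T @ gy
        self.grads["b"] += gy.sum(axis=0)
        return gy @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, train)
            caches.append(c)
        return x, caches

    def backward(self, caches, gy):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            gy = layer.backward(c, gy)
        return gy

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    # -- parameter plumbing -------------------------------------------------
    def named_params(self):
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                for name, l, key in layer.named_params():
                    yield f"{i}.{name}", l, key
            else:
                for key in layer.params:
                    yield f"{i}.{key}", layer, key

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer, key in self.named_params():
            out[name] = layer.params[key].copy()
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1d):
                out[f"{i}.running_mean"] = layer.running_mean.copy()
                out[f"{i}.running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.named_params():
            if name not in state:
                raise KeyError(f"missing parameter {name} in state dict")
            if layer.params[key].shape != state[name].shape:
                raise ValueError(
                    f"parameter {name}: checkpoint shape {state[name].shape} "
                    f"!= model shape {layer.params[key].shape}"
                )
            layer.params[key] = state[name].copy()
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1d):
                if f"{i}.running_mean" in state:
                    layer.running_mean = state[f"{i}.running_mean"].copy()
                    layer.running_var = state[f"{i}.running_var"].copy()


class Adam:
    """Adam optimizer over the parameters of one or more Sequentials."""

    def __init__(self, modules: list[Sequential], lr: float = 0.001,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.slots = []
        for mod in modules:
            for name, layer, key in mod.named_params():
                self.slots.append((layer, key,
                                   np.zeros_like(layer.params[key]),
                                   np.zeros_like(layer.params[key])))
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for layer, key, m, v in self.slots:
            g = layer.grads[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grads(self) -> None:
        for layer, key, _, _ in self.slots:
            layer.grads[key] = np.zeros_like(layer.params[key])


class frozen_running_stats:
    """Context manager: train-mode forwards inside it use batch statistics
    as usual but leave the running (evaluation) statistics untouched."""

    def __init__(self, *modules: Sequential):
        self.bns = [layer for mod in modules for layer in mod.layers
                    if isinstance(layer, BatchNorm1d)]

    def __enter__(self):
        for bn in self.bns:
            bn.track_running = False
        return self

    def __exit__(self, *exc):
        for bn in self.bns:
            bn.track_running = True
        return False


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, grad wrt logits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return float(loss), g / n
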