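"""Minimal CNN engine on numpy: layers with explicit forward/backward,
SGD/Adam updaters, and softmax cross-entropy.

Convolution and max-pooling are im2col-based (sliding_window_view + one
matmul), which keeps the arithmetic in BLAS. Tensors are NCHW float32.
Every layer owns its parameters as `Param` objects; optimizers mutate
`Param.data` in place. Batch-norm parameters are flagged `decay=False`
so L2 weight decay skips them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "ParallelConcat",
    "Residual",
    "Network",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
    "Adam",
    "make_rng",
]


def make_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class Param:
    name: str
    data: np.ndarray
    grad: np.ndarray = field(init=False)
    decay: bool = True  # participates in L2 weight decay

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.data)


class Layer:
    """Base layer: forward caches what backward needs; backward returns
    the gradient w.r.t. the layer input and accumulates parameter grads."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


class Conv2d(Layer):
    """2-D convolution (cross-correlation), optional bias.

    Output spatial dims follow floor((in + 2*pad - kernel)/stride) + 1.
    Weights use Kaiming-uniform fan-in initialization.
    """

    def __init__(self, in_channels, out_channels, kernel, stride=1, padding=0,
                 bias=False, rng=None, name="conv"):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        self.ph, self.pw = _pair(padding)
        rng = make_rng(rng)
        fan_in = in_channels * self.kh * self.kw
        bound = np.sqrt(6.0 / fan_in)
        w = rng.uniform(-bound, bound, (out_channels, in_channels, self.kh, self.kw))
        self.weight = Param(f"{name}.weight", w.astype(np.float32))
        self.bias = Param(f"{name}.bias", np.zeros(out_channels, np.float32)) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _out_hw(self, H, W):
        oh = (H + 2 * self.ph - self.kh) // self.sh + 1
        ow = (W + 2 * self.pw - self.kw) // self.sw + 1
        if oh < 1 or ow < 1:
            raise ValueError(
                f"{self.weight.name}: non-positive output dims for input {H}x{W}"
            )
        return oh, ow

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        oh, ow = self._out_hw(H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        win = win[:, :, :: self.sh, :: self.sw]  # N,C,oh,ow,kh,kw
        dtype = np.result_type(x.dtype, self.weight.data.dtype)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * oh * ow, C * self.kh * self.kw)
        cols = np.ascontiguousarray(cols, dtype=dtype)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        out = out.reshape(N, oh, ow, self.out_channels).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape, (oh, ow))
        return np.ascontiguousarray(out)

    def backward(self, grad):
        cols, (N, C, H, W), (oh, ow) = self._cache
        gmat = grad.transpose(0, 2, 3, 1).reshape(N * oh * ow, self.out_channels)
        self.weight.grad += (gmat.T @ cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += gmat.sum(axis=0)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        dcols = (gmat @ wmat).reshape(N, oh, ow, C, self.kh, self.kw)
        dxp = np.zeros((N, C, H + 2 * self.ph, W + 2 * self.pw), dcols.dtype)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # N,C,oh,ow,kh,kw
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + self.sh * oh : self.sh,
                    j : j + self.sw * ow : self.sw] += dcols[:, :, :, :, i, j]
        if self.ph or self.pw:
            return dxp[:, :, self.ph : self.ph + H, self.pw : self.pw + W]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, channels, momentum=0.1, eps=1e-5, name="bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(channels, np.float32), )
        self.beta = Param(f"{name}.beta", np.zeros(channels, np.float32))
        self.gamma.decay = False
        self.beta.decay = False
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._cache = None
        self._stats_acc = None

    def params(self):
        return [self.gamma, self.beta]

    def begin_stats_accumulation(self):
        """Start collecting exact population statistics (see Network
        .recalibrate_bn)."""
        self._stats_acc = [0, 0.0, 0.0]  # count, sum, sum of squares

    def end_stats_accumulation(self):
        n, s, ss = self._stats_acc
        self.running_mean = (s / n).astype(np.float32)
        self.running_var = np.maximum(ss / n - (s / n) ** 2, 0.0).astype(np.float32)
        self._stats_acc = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            if self._stats_acc is not None:
                m = x.shape[0] * x.shape[2] * x.shape[3]
                self._stats_acc[0] += m
                self._stats_acc[1] += x.sum(axis=(0, 2, 3), dtype=np.float64)
                self._stats_acc[2] += (x.astype(np.float64) ** 2).sum(axis=(0, 2, 3))
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        self._cache = (xhat, inv_std, x.shape)
        return self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]

    def backward(self, grad):
        xhat, inv_std, shape = self._cache
        N, C, H, W = shape
        m = N * H * W
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[:, None, None]
        # backward through the batch statistics
        mean_g = g.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        dx = (g - mean_g - xhat * mean_gx) * inv_std[:, None, None]
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel, stride, padding=0):
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        self.ph, self.pw = _pair(padding)

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        win = win[:, :, :: self.sh, :: self.sw]
        N_, C_, oh, ow = win.shape[:4]
        flat = win.reshape(N, C, oh, ow, self.kh * self.kw)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        self._out_hw = (oh, ow)
        return np.ascontiguousarray(flat.max(axis=-1).astype(np.float32))

    def backward(self, grad):
        N, C, H, W = self._in_shape
        oh, ow = self._out_hw
        dxp = np.zeros((N, C, H + 2 * self.ph, W + 2 * self.pw), np.float32)
        for k in range(self.kh * self.kw):
            i, j = divmod(k, self.kw)
            sel = (self._argmax == k) * grad
            dxp[:, :, i : i + self.sh * oh : self.sh,
                j : j + self.sw * ow : self.sw] += sel
        if self.ph or self.pw:
            return dxp[:, :, self.ph : self.ph + H, self.pw : self.pw + W]
        return dxp


class GlobalAvgPool(Layer):
    """Adaptive average pool to 1×1, flattened to (N, C)."""

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        N, C, H, W = self._in_shape
        return np.broadcast_to(
            grad[:, :, None, None] / (H * W), self._in_shape
        ).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features, out_features, rng=None, name="fc"):
        rng = make_rng(rng)
        bound = np.sqrt(6.0 / in_features)
        w = rng.uniform(-bound, bound, (out_features, in_features))
        self.weight = Param(f"{name}.weight", w.astype(np.float32))
        self.bias = Param(f"{name}.bias", np.zeros(out_features, np.float32))
        self.bias.decay = False

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class ParallelConcat(Layer):
    """Inception-style block: run branches in parallel on the same input and
    concatenate their outputs along the channel axis."""

    def __init__(self, *branches):
        self.branches = list(branches)

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def forward(self, x, train=False):
        outs = [b.forward(x, train) for b in self.branches]
        hw = {o.shape[2:] for o in outs}
        if len(hw) != 1:
            raise ValueError(f"branch spatial dims disagree: {sorted(hw)}")
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        grads = np.split(grad, self._splits, axis=1)
        total = None
        for b, g in zip(self.branches, grads):
            gx = b.backward(np.ascontiguousarray(g))
            total = gx if total is None else total + gx
        return total


class Residual(Layer):
    """y = ReLU(F(x) + S(x)); S is identity when `shortcut` is None."""

    def __init__(self, main: Layer, shortcut: Layer | None = None):
        self.main = main
        self.shortcut = shortcut
        self._relu = ReLU()

    def params(self):
        ps = self.main.params()
        if self.shortcut is not None:
            ps = ps + self.shortcut.params()
        return ps

    def forward(self, x, train=False):
        f = self.main.forward(x, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        if f.shape != s.shape:
            raise ValueError(f"residual shape mismatch: F {f.shape} vs shortcut {s.shape}")
        return self._relu.forward(f + s, train)

    def backward(self, grad):
        g = self._relu.backward(grad)
        gx = self.main.backward(g)
        if self.shortcut is None:
            return gx + g
        return gx + self.shortcut.backward(g)


class Network(Layer):
    """Named sequence of blocks with checkpointing support."""

    def __init__(self, blocks: list[tuple[str, Layer]]):
        self.blocks = blocks

    def params(self):
        return [p for _, b in self.blocks for p in b.params()]

    def forward(self, x, train=False):
        for _, b in self.blocks:
            x = b.forward(x, train)
        return x

    def backward(self, grad):
        for _, b in reversed(self.blocks):
            grad = b.backward(grad)
        return grad

    def forward_trace(self, x, train=False) -> list[tuple[str, tuple]]:
        """Run forward, recording each block's output shape (sans batch)."""
        trace = []
        for name, b in self.blocks:
            x = b.forward(x, train)
            trace.append((name, tuple(x.shape[1:])))
        return trace

    def _bn_layers(self):
        stack = [b for _, b in self.blocks]
        while stack:
            l = stack.pop()
            if isinstance(l, BatchNorm2d):
                yield l
            for attr in ("layers", "branches"):
                stack.extend(getattr(l, attr, []))
            if isinstance(l, Residual):
                stack.append(l.main)
                if l.shortcut is not None:
                    stack.append(l.shortcut)

    def recalibrate_bn(self, X: np.ndarray, batch_size: int = 64) -> None:
        """Replace every batch-norm layer's running statistics with the
        exact population statistics of the given (training) inputs under
        the current weights. Running estimates lag the weights during fast
        optimization; recalibrating before inference-mode evaluation
        removes that train/eval statistics mismatch."""
        bns = list(self._bn_layers())
        if not bns:
            return
        for bn in bns:
            bn.begin_stats_accumulation()
        for i in range(0, len(X), batch_size):
            self.forward(X[i: i + batch_size], train=True)
        for bn in bns:
            bn.end_stats_accumulation()

    def state_dict(self) -> dict:
        state = {p.name: p.data.copy() for p in self.params()}
        for i, bn in enumerate(self._bn_layers()):
            state[f"__running__.{i}.mean"] = bn.running_mean.copy()
            state[f"__running__.{i}.var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for p in self.params():
            p.data = state[p.name].copy()
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean = state[f"__running__.{i}.mean"].copy()
            bn.running_var = state[f"__running__.{i}.var"].copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class SGD:
    """Plain (momentum-free) stochastic gradient descent with coupled L2
    weight decay on decay-flagged parameters."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p in self.params:
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.data
            p.data -= self.lr * g


class Adam:
    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.data
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
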