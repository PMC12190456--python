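"""Layer primitives with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
consumes the cache in ``backward``; a module must therefore be re-forwarded
before each backward call (shared backbones re-run the forward per ROI
branch before backpropagating that branch's gradient).
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=_DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter discovery, train/eval mode, call syntax."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, out: list[Parameter], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, out, seen)

    @staticmethod
    def _collect_value(value, out: list[Parameter], seen: set[int]) -> None:
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                out.append(value)
        elif isinstance(value, Module):
            value._collect(out, seen)
        elif isinstance(value, (list, tuple)):
            for item in value:
                Module._collect_value(item, out, seen)

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in vars(self).values():
            self._set_mode(value, mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    @staticmethod
    def _set_mode(value, mode: bool) -> None:
        if isinstance(value, Module):
            value.train(mode)
        elif isinstance(value, (list, tuple)):
            for item in value:
                Module._set_mode(item, mode)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {arr.shape}")
            p.data[...] = arr

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)


def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    b, c = xp.shape[:2]
    cols = np.empty((b, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols


def _col2im(dcols: np.ndarray, xp_shape: tuple[int, ...], k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, :, i, j]
    return dxp


class Conv2d(Module):
    """2-D convolution with square kernels; supports grouped/depthwise form."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        cg = in_channels // groups
        fan_in = cg * kernel_size * kernel_size
        self.weight = Parameter(_he_normal(rng, (out_channels, cg, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s, p, g = self.kernel_size, self.stride, self.padding, self.groups
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (xp.shape[2] - k) // s + 1
        wo = (xp.shape[3] - k) // s + 1
        cols = _im2col(xp, k, s, ho, wo)
        colsg = cols.reshape(b, g, c // g, k, k, ho, wo)
        wg = self.weight.data.reshape(g, self.out_channels // g, c // g, k, k)
        out = np.einsum("bgcijhw,gocij->bgohw", colsg, wg, optimize=True)
        out = out.reshape(b, self.out_channels, ho, wo)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (colsg, xp.shape, ho, wo)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        colsg, xp_shape, ho, wo = self._cache
        b = grad.shape[0]
        k, s, p, g = self.kernel_size, self.stride, self.padding, self.groups
        c = self.in_channels
        gg = grad.reshape(b, g, self.out_channels // g, ho, wo)
        wg = self.weight.data.reshape(g, self.out_channels // g, c // g, k, k)
        self.weight.grad += np.einsum("bgohw,bgcijhw->gocij", gg, colsg, optimize=True).reshape(
            self.weight.data.shape
        )
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        dcols = np.einsum("bgohw,gocij->bgcijhw", gg, wg, optimize=True).reshape(b, c, k, k, ho, wo)
        dxp = _col2im(dcols, xp_shape, k, s, ho, wo)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * (n / max(n - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(_DTYPE)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.weight.data[None, :, None, None] * xhat + self.bias.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        axes = (0, 2, 3)
        self.weight.grad += (grad * xhat).sum(axis=axes)
        self.bias.grad += grad.sum(axis=axes)
        g = grad * self.weight.data[None, :, None, None]
        if not self.training:
            return g / std[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        gm = g.mean(axis=axes)[None, :, None, None]
        gxm = (g * xhat).mean(axis=axes)[None, :, None, None]
        return (g - gm - xhat * gxm) / std[None, :, None, None]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features)) if bias else None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = _sigmoid(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class SiLU(Module):
    """x * sigmoid(x) — the swish activation used throughout EfficientNet."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._s = _sigmoid(x)
        return x * self._s

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self._s
        return grad * (s + self._x * s * (1.0 - s))


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        b, c = xp.shape[:2]
        ho = (xp.shape[2] - k) // s + 1
        wo = (xp.shape[3] - k) // s + 1
        cols = _im2col(xp, k, s, ho, wo).reshape(b, c, k * k, ho, wo)
        idx = cols.argmax(axis=2)
        out = np.take_along_axis(cols, idx[:, :, None], axis=2)[:, :, 0]
        self._cache = (idx, xp.shape, x.shape, ho, wo)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, xp_shape, x_shape, ho, wo = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        b, c = grad.shape[:2]
        dcols = np.zeros((b, c, k * k, ho, wo), dtype=grad.dtype)
        np.put_along_axis(dcols, idx[:, :, None], grad[:, :, None], axis=2)
        dxp = _col2im(dcols.reshape(b, c, k, k, ho, wo), xp_shape, k, s, ho, wo)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool2d(Module):
    """Spatial mean: (B, C, H, W) -> (B, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).astype(grad.dtype).copy()


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad


class SqueezeExcite(Module):
    """Channel attention: pool -> reduce FC -> SiLU -> expand FC -> sigmoid gate.

    Parameter layout matches the 1x1-convolution formulation (both FCs carry
    biases), so architecture parameter counts line up with the published ones.
    """

    def __init__(self, channels: int, squeeze_channels: int, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.fc1 = Linear(channels, squeeze_channels, bias=True, rng=rng)
        self.act = SiLU()
        self.fc2 = Linear(squeeze_channels, channels, bias=True, rng=rng)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pooled = x.mean(axis=(2, 3))
        gate = _sigmoid(self.fc2(self.act(self.fc1(pooled))))
        self._cache = (x, gate)
        return x * gate[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, gate = self._cache
        h, w = x.shape[2], x.shape[3]
        dgate = (grad * x).sum(axis=(2, 3)) * gate * (1.0 - gate)
        dpooled = self.fc1.backward(self.act.backward(self.fc2.backward(dgate)))
        dx = grad * gate[:, :, None, None]
        dx += dpooled[:, :, None, None] / (h * w)
        return dx


class Residual(Module):
    """y = post_act(main(x) + shortcut(x)); identity shortcut when None."""

    def __init__(self, main: Module, shortcut: Module | None = None, post_act: Module | None = None):
        self.main = main
        self.shortcut = shortcut
        self.post_act = post_act

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.main(x) + (self.shortcut(x) if self.shortcut is not None else x)
        if self.post_act is not None:
            out = self.post_act(out)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.post_act is not None:
            grad = self.post_act.backward(grad)
        dmain = self.main.backward(grad)
        dshort = self.shortcut.backward(grad) if self.shortcut is not None else grad
        return dmain + dshort
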