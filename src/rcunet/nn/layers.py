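"""Minimal NumPy neural-network layers with hand-written backward passes.

All tensors are NCHW float64 arrays. Every layer caches what its backward
pass needs only when ``training`` is enabled, so inference on large inputs
stays memory-light. Backward passes accumulate into ``Parameter.grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# Training runs in float32 by default (the usual choice for conv nets and
# roughly twice the BLAS throughput of float64); switch to float64 for
# high-precision work such as finite-difference gradient verification.
_DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global _DEFAULT_DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE = dtype


def get_default_dtype():
    return _DEFAULT_DTYPE


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape


class Module:
    """Base class: child modules/parameters register via attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, child in self._children.items():
            yield from child.named_parameters(prefix + name + ".")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        for name, arr in state.items():
            if name not in own:
                raise KeyError(f"unknown parameter {name!r}")
            if own[name].data.shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: "
                    f"{own[name].data.shape} vs {arr.shape}"
                )
            own[name].data[...] = arr
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (C*kh*kw, N*H*W) patch matrix, zero padded.

    The channels-first layout makes the gather a series of contiguous
    row copies, which is markedly faster than per-patch gathers.
    """
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = sliding_window_view(x, (kh, kw), axis=(2, 3))
    # (N, C, H, W, kh, kw) -> (C, kh, kw, N, H, W) then flatten
    cols = cols.transpose(1, 4, 5, 0, 2, 3)
    return cols.reshape(c * kh * kw, n * h * w)


class Conv2d(Module):
    """Stride-1, odd-kernel, zero same-padded 2-D convolution (cross-correlation)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 bias: bool = True):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes only")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.weight = Parameter(
            np.zeros((out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._cache = None

    @property
    def fan_in(self) -> int:
        return self.in_channels * self.kernel_size ** 2

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.kernel_size
        cols = _im2col(x, k, k, k // 2)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        y = wmat @ cols  # (Co, N*H*W)
        if self.bias is not None:
            y += self.bias.data[:, None]
        y = y.reshape(self.out_channels, n, h, w).transpose(1, 0, 2, 3)
        if self.training:
            self._cache = (cols, (n, c, h, w))
        return np.ascontiguousarray(y)

    def backward(self, grad):
        cols, (n, c, h, w) = self._cache
        self._cache = None
        k = self.kernel_size
        g = np.ascontiguousarray(grad.transpose(1, 0, 2, 3)).reshape(
            self.out_channels, n * h * w)
        self.weight.grad += (g @ cols.T).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=1)
        # input gradient = same-padded convolution of grad with the
        # 180deg-rotated kernel, input/output channels swapped
        w_rot = self.weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        gcols = _im2col(grad, k, k, k // 2)  # (Co*k*k, N*H*W)
        gx = w_rot.reshape(self.in_channels, -1) @ gcols
        return np.ascontiguousarray(
            gx.reshape(self.in_channels, n, h, w).transpose(1, 0, 2, 3))


class ConvTranspose2d(Module):
    """2x2-kernel, stride-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = 2
        self.weight = Parameter(np.zeros((in_channels, out_channels, 2, 2)))
        self.bias = Parameter(np.zeros(out_channels))
        self._cache = None

    @property
    def fan_in(self) -> int:
        return self.in_channels * self.kernel_size ** 2

    def forward(self, x):
        n, c, h, w = x.shape
        t = np.tensordot(x, self.weight.data, axes=([1], [0]))  # N,H,W,Co,2,2
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.out_channels,
                                                  2 * h, 2 * w)
        y = y + self.bias.data[None, :, None, None]
        if self.training:
            self._cache = x
        return np.ascontiguousarray(y)

    def backward(self, grad):
        x = self._cache
        self._cache = None
        n, c, h, w = x.shape
        gr = grad.reshape(n, self.out_channels, h, 2, w, 2)
        gr = np.ascontiguousarray(gr.transpose(0, 2, 4, 1, 3, 5))  # N,H,W,Co,2,2
        self.weight.grad += np.tensordot(x, gr, axes=([0, 2, 3], [0, 1, 2]))
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        gx = np.tensordot(gr, self.weight.data, axes=([3, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(gx.transpose(0, 3, 1, 2))


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DEFAULT_DTYPE)
        self.running_var = np.ones(channels, dtype=_DEFAULT_DTYPE)
        self._cache = None

    def forward(self, x):
        if self.training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = (xhat, inv, x.shape)
            return (self.gamma.data[None, :, None, None] * xhat
                    + self.beta.data[None, :, None, None])
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (self.gamma.data[None, :, None, None]
                * (x - self.running_mean[None, :, None, None])
                * inv[None, :, None, None]
                + self.beta.data[None, :, None, None])

    def backward(self, grad):
        xhat, inv, shape = self._cache
        self._cache = None
        n, c, h, w = shape
        m = n * h * w
        axes = (0, 2, 3)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gxhat = grad * self.gamma.data[None, :, None, None]
        gx = (gxhat
              - gxhat.mean(axis=axes)[None, :, None, None]
              - xhat * (gxhat * xhat).mean(axis=axes)[None, :, None, None])
        return gx * inv[None, :, None, None]


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        mask = x > 0
        if self.training:
            self._mask = mask
        return np.where(mask, x, 0.0)

    def backward(self, grad):
        mask = self._mask
        self._mask = None
        return np.where(mask, grad, 0.0)


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._out = None

    def forward(self, x):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        if self.training:
            self._out = out
        return out

    def backward(self, grad):
        out = self._out
        self._out = None
        return grad * out * (1.0 - out)


class MaxPool2d(Module):
    """2x2 max pooling with stride 2."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if self.training:
            self._cache = (idx, (n, c, h, w))
        return y

    def backward(self, grad):
        idx, (n, c, h, w) = self._cache
        self._cache = None
        g4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(g4, idx[..., None], grad[..., None], axis=-1)
        g4 = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(g4).reshape(n, c, h, w)


class Identity(Module):
    def forward(self, x):
        return x

    def backward(self, grad):
        return grad


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
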