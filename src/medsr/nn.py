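"""Minimal CNN building blocks with explicit forward/backward passes.

All layers operate on float32 arrays in NCHW layout (batch, channels,
height, width).  Each layer caches what its backward pass needs during
``forward`` and releases it after ``backward``; layers are therefore not
re-entrant, which is fine for a plain training loop.

Weight initialisation is Kaiming-uniform over fan-in (bound
``sqrt(6 / fan_in)``), biases start at zero, BatchNorm starts at
scale 1 / shift 0.  Every layer draws its weights from the RNG handed to
its constructor, so a model built twice from the same seed is bitwise
identical.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: traverses attributes to collect params and buffers."""

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for value in vars(self).values():
            if isinstance(value, Param):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        """Non-trainable state (BatchNorm running statistics)."""
        out: list[tuple[str, np.ndarray]] = []
        for value in vars(self).values():
            if isinstance(value, Module):
                out.extend(value.buffers())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.buffers())
        return out


def _pad_hw(x: np.ndarray, pad: int, value: float = 0.0) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(
        x,
        ((0, 0), (0, 0), (pad, pad), (pad, pad)),
        mode="constant",
        constant_values=value,
    )


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, Ho, Wo, C*k*k) patch matrix (a view-copy)."""
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    n, c, ho, wo = windows.shape[:4]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2d(Module):
    """2-D convolution (cross-correlation) with bias.

    Stride-1 convs use `same` padding k//2 by default so the trunk
    preserves spatial size; the ESA downsampling conv uses stride 2.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
        name: str = "conv",
    ):
        if kernel not in (1, 3):
            raise ValueError(f"kernel must be 1 or 3, got {kernel}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_channels * kernel * kernel
        bound = np.sqrt(6.0 / fan_in)
        w = rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel, kernel))
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(out_channels))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        xp = _pad_hw(x, p)
        cols = _im2col(xp, k, s)  # (N, Ho, Wo, Cin*k*k)
        wmat = self.weight.data.reshape(self.out_channels, -1)  # (Cout, Cin*k*k)
        out = cols @ wmat.T + self.bias.data
        self._cache = (x.shape, cols)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        self._cache = None
        k, s, p = self.kernel, self.stride, self.padding
        n, _, ho, wo = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
        self.weight.grad += (g.T @ cols.reshape(-1, cols.shape[-1])).reshape(
            self.weight.data.shape
        )
        self.bias.grad += g.sum(axis=0)

        # dx: zero-stuff the gradient by the stride, then full-correlate
        # with the spatially flipped, channel-transposed kernel.
        hi, wi = x_shape[2], x_shape[3]
        hp, wp = hi + 2 * p, wi + 2 * p
        gup = np.zeros((n, self.out_channels, hp - k + 1, wp - k + 1), dtype=DTYPE)
        gup[:, :, ::s, ::s] = grad[:, :, :ho, :wo]
        w_rot = self.weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        gpad = _pad_hw(gup, k - 1)
        cols_g = _im2col(gpad, k, 1)
        dxp = cols_g @ w_rot.reshape(self.in_channels, -1).T
        dxp = dxp.transpose(0, 3, 1, 2)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return np.ascontiguousarray(dxp)

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by batch moments over (N, H, W) and updates
    the running mean/var (momentum 0.1, population variance); eval mode
    uses the running statistics.
    """

    def __init__(self, channels: int, name: str = "bn", eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._name = name
        self._cache = None

    def buffers(self):
        return [
            (f"{self._name}.running_mean", self.running_mean),
            (f"{self._name}.running_var", self.running_var),
        ]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean.astype(DTYPE) - self.running_mean)
            self.running_var += self.momentum * (var.astype(DTYPE) - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        out = self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]
        self._cache = (xhat, inv_std, training, x.shape)
        return out.astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, shape = self._cache
        self._cache = None
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gscaled = grad * self.gamma.data[:, None, None]
        if not training:
            return gscaled * inv_std[:, None, None]
        m = shape[0] * shape[2] * shape[3]
        # standard batchnorm backward through the batch moments
        dxhat_sum = gscaled.sum(axis=(0, 2, 3))
        dxhat_dot = (gscaled * xhat).sum(axis=(0, 2, 3))
        dx = (
            gscaled
            - dxhat_sum[:, None, None] / m
            - xhat * dxhat_dot[:, None, None] / m
        ) * inv_std[:, None, None]
        return dx.astype(DTYPE)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, grad, 0.0).astype(DTYPE)


class Sigmoid(Module):
    def __init__(self):
        self._out = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):  # saturation is well-defined
            out = 1.0 / (1.0 + np.exp(-x, dtype=np.float64))
        self._out = out.astype(DTYPE)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out, self._out = self._out, None
        return (grad * out * (1.0 - out)).astype(DTYPE)


class MaxPool2d(Module):
    """Max pooling; padding uses -inf so padded cells never win."""

    def __init__(self, kernel: int, stride: int, padding: int = 0):
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        xp = _pad_hw(x, p, value=-np.inf)
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        windows = windows[:, :, ::s, ::s]
        n, c, ho, wo = windows.shape[:4]
        flat = windows.reshape(n, c, ho, wo, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, xp.shape, arg)
        return np.ascontiguousarray(out.astype(DTYPE))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, arg = self._cache
        self._cache = None
        k, s, p = self.kernel, self.stride, self.padding
        n, c, ho, wo = grad.shape
        dxp = np.zeros((n, c) + xp_shape[2:], dtype=DTYPE)
        # window top-left corners
        oy = (np.arange(ho) * s)[:, None]
        ox = (np.arange(wo) * s)[None, :]
        ky, kx = np.divmod(arg, k)
        rows = (oy[None, None] + ky).reshape(n, c, -1)
        cols = (ox[None, None] + kx).reshape(n, c, -1)
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dxp, (ni, ci, rows, cols), grad.reshape(n, c, -1))
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1


def _linear_resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers)."""
    mat = np.zeros((n_out, n_in), dtype=DTYPE)
    if n_in == 1:
        mat[:, 0] = 1.0
        return mat
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(DTYPE)
    mat[np.arange(n_out), lo] += 1.0 - frac
    mat[np.arange(n_out), hi] += frac
    return mat


class BilinearResize(Module):
    """Resize to an arbitrary target size; linear, hence an exact-transpose
    backward.  Matrices are cached per (in, out) size pair."""

    def __init__(self):
        self._mats: dict[tuple[int, int], np.ndarray] = {}
        self._cache = None

    def _mat(self, n_out: int, n_in: int) -> np.ndarray:
        key = (n_out, n_in)
        if key not in self._mats:
            self._mats[key] = _linear_resize_matrix(n_out, n_in)
        return self._mats[key]

    def forward(self, x: np.ndarray, size: tuple[int, int]) -> np.ndarray:
        hi, wi = x.shape[2], x.shape[3]
        ho, wo = size
        rmat = self._mat(ho, hi)
        cmat = self._mat(wo, wi)
        out = np.einsum("ij,ncjk,lk->ncil", rmat, x, cmat, optimize=True)
        self._cache = (rmat, cmat)
        return np.ascontiguousarray(out.astype(DTYPE))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        rmat, cmat = self._cache
        self._cache = None
        dx = np.einsum("ji,ncjk,kl->ncil", rmat, grad, cmat, optimize=True)
        return np.ascontiguousarray(dx.astype(DTYPE))


class PixelShuffle(Module):
    """Rearrange (N, C*r^2, H, W) -> (N, C, rH, rW); the sub-pixel upsampler."""

    def __init__(self, r: int):
        self.r = r

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, crr, h, w = x.shape
        r = self.r
        c = crr // (r * r)
        if c * r * r != crr:
            raise ValueError(f"channels {crr} not divisible by r^2={r*r}")
        out = x.reshape(n, c, r, r, h, w).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(out.reshape(n, c, h * r, w * r))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, hr, wr = grad.shape
        r = self.r
        h, w = hr // r, wr // r
        g = grad.reshape(n, c, h, r, w, r).transpose(0, 1, 3, 5, 2, 4)
        return np.ascontiguousarray(g.reshape(n, c * r * r, h, w))


class Adam:
    """Adam with bias correction over a flat list of Params."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 5e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
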