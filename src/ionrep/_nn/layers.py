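"""Layers with explicit forward/backward passes on float64 NumPy arrays.

Conventions: inputs are (B, C, H, W) for 2-D layers and (B, F) for 1-D
layers.  ``forward(x, train)`` caches what ``backward(grad)`` needs;
``backward`` accumulates into each parameter's ``.grad`` and returns the
gradient with respect to the layer input.  A module instance therefore holds
one in-flight forward at a time (the trainer concatenates both augmented
views into a single batch, so this is never limiting).
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        return []

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train)


# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    B, C, H, W = x.shape
    oh = (H - k) // stride + 1
    ow = (W - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(B, C, k, k, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(windows.transpose(0, 4, 5, 1, 2, 3))
    return cols.reshape(B * oh * ow, C * k * k), oh, ow


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int, oh: int, ow: int):
    B, C, H, W = xshape
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
    d6 = dcols.reshape(B, oh, ow, C, k, k).transpose(0, 3, 4, 5, 1, 2)  # B,C,k,k,oh,ow
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + oh * stride : stride, kj : kj + ow * stride : stride] += d6[
                :, :, ki, kj
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    """Same-style convolution via im2col; no bias (a BN layer follows)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 init_std: float = 0.02):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, init_std, size=(c_out, c_in * k * k)))

    def forward(self, x, train=True):
        self._xshape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._oh, self._ow = cols, oh, ow
        y = cols @ self.w.value.T
        B = x.shape[0]
        return y.reshape(B, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        B = self._xshape[0]
        gflat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.w.grad += gflat.T @ self._cols
        dcols = gflat @ self.w.value
        return _col2im(dcols, self._xshape, self.k, self.stride, self.pad, self._oh, self._ow)

    def params(self):
        return [self.w]


class _BatchNorm(Module):
    def __init__(self, n: int, momentum: float = 0.1):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum

    _axes: tuple  # reduction axes; set by subclass

    def _shape(self, v):
        raise NotImplementedError

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - self._shape(mean)) * self._shape(invstd)
        self._xhat, self._invstd, self._train = xhat, invstd, train
        self._n = x.size // x.shape[1]
        return self._shape(self.gamma.value) * xhat + self._shape(self.beta.value)

    def backward(self, grad):
        xhat, invstd = self._xhat, self._invstd
        self.gamma.grad += (grad * xhat).sum(axis=self._axes)
        self.beta.grad += grad.sum(axis=self._axes)
        dxhat = grad * self._shape(self.gamma.value)
        if not self._train:
            return dxhat * self._shape(invstd)
        n = self._n
        t = (
            n * dxhat
            - self._shape(dxhat.sum(axis=self._axes))
            - xhat * self._shape((dxhat * xhat).sum(axis=self._axes))
        )
        return t * self._shape(invstd) / n

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]


class BatchNorm2d(_BatchNorm):
    _axes = (0, 2, 3)

    def _shape(self, v):
        return v[None, :, None, None]


class BatchNorm1d(_BatchNorm):
    _axes = (0,)

    def _shape(self, v):
        return v[None, :]


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class MaxPool2d(Module):
    """2x2 max pooling, stride 2 (inputs are padded to even sides upstream)."""

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        xr = (
            x.reshape(B, C, H // 2, 2, W // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H // 2, W // 2, 4)
        )
        self._arg = xr.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        B, C, H, W = self._xshape
        buf = np.zeros((B, C, H // 2, W // 2, 4))
        np.put_along_axis(buf, self._arg[..., None], grad[..., None], axis=-1)
        return (
            buf.reshape(B, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H, W)
        )


class GlobalAvgPool(Module):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x, train=True):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._xshape
        return np.broadcast_to(grad[:, :, None, None], self._xshape) / (H * W)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, init_std, size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out)) if bias else None

    def forward(self, x, train=True):
        self._x = x
        y = x @ self.w.value.T
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self):
        return [b for layer in self.layers for b in layer.buffers()]


class ResidualBlock(Module):
    """conv-BN-ReLU-conv-BN with identity (or 1x1-projected) skip, ReLU out.

    ``final_relu=False`` omits the output rectifier, leaving the block's sum
    sign-symmetric — used for the trunk's last block so pooled features are
    not confined to the positive orthant.
    """

    def __init__(self, c_in: int, c_out: int, stride: int = 1,
                 rng: np.random.Generator | None = None, init_std: float = 0.02,
                 final_relu: bool = True):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(c_in, c_out, 3, stride, rng=rng, init_std=init_std)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, rng=rng, init_std=init_std)
        self.bn2 = BatchNorm2d(c_out)
        self.relu_out = ReLU() if final_relu else None
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride, pad=0, rng=rng, init_std=init_std)
            self.proj_bn = BatchNorm2d(c_out)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x, train=True):
        y = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train),
                train,
            ),
            train,
        )
        if self.proj is not None:
            skip = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            skip = x
        out = y + skip
        return self.relu_out.forward(out, train) if self.relu_out is not None else out

    def backward(self, grad):
        g = self.relu_out.backward(grad) if self.relu_out is not None else grad
        g_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g))))
        )
        if self.proj is not None:
            g_skip = self.proj.backward(self.proj_bn.backward(g))
        else:
            g_skip = g
        return g_main + g_skip

    def params(self):
        mods = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            mods += [self.proj, self.proj_bn]
        return [p for m in mods for p in m.params()]

    def buffers(self):
        mods = [self.bn1, self.bn2] + ([self.proj_bn] if self.proj_bn is not None else [])
        return [b for m in mods for b in m.buffers()]
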