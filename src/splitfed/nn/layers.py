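"""Neural-network modules built on the autograd tensors.

Parameter initialization is deterministic: every module takes a
``numpy.random.Generator`` (or seed) at construction, so identical seeds
give bit-identical models. Keras-style 'same' padding semantics are used
for strided (transposed) convolutions so that feature-map shapes match the
architecture tables this package reproduces.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import tensor as T
from .tensor import Tensor


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(T.get_default_dtype())


def he_normal(rng: np.random.Generator, shape, fan_in: int):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(
        T.get_default_dtype())


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # ------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ------------------------------------------------------------ state dict
    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        out = OrderedDict()
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, b in self.named_buffers():
            out[name] = np.array(b, copy=True)
        return out

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffer_owners = {}
        for mname, m in self._named_modules(""):
            for bname in m._buffers:
                buffer_owners[(mname + "." if mname else "") + bname] = (m, bname)
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {name!r}")
                params[name].data = value.astype(params[name].data.dtype, copy=True)
            elif name in buffer_owners:
                m, bname = buffer_owners[name]
                m._set_buffer(bname, np.array(value, copy=True))
            else:
                raise KeyError(f"unknown entry {name!r} in state dict")

    def _named_modules(self, prefix: str):
        yield prefix, self
        for mname, m in self._modules.items():
            yield from m._named_modules((prefix + "." if prefix else "") + mname)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._order = list(mods)

    def forward(self, x):
        for m in self._order:
            x = m(x)
        return x


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng, init: str = "glorot"):
        super().__init__()
        rng = _as_rng(rng)
        w = (he_normal(rng, (n_in, n_out), n_in) if init == "he"
             else glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(n_out, dtype=T.get_default_dtype()))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    """Label embedding, unit-scale normal init.

    The unit scale matters: label-conditioning signals must start on the
    same footing as image/latent activations, or a discriminator that can
    already win unconditionally never learns to use the label at all.
    """

    def __init__(self, n_vocab: int, dim: int, rng):
        super().__init__()
        rng = _as_rng(rng)
        self.weight = Parameter(
            rng.normal(0.0, 1.0, size=(n_vocab, dim)).astype(T.get_default_dtype()))

    def forward(self, idx) -> Tensor:
        return T.embedding(self.weight, idx)


def same_pads(size: int, kernel: int, stride: int):
    """Keras 'same' padding for one spatial axis: output = ceil(size/stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    lo = total // 2
    return lo, total - lo


class Conv2d(Module):
    """NCHW convolution; padding 'same', 'valid' or an integer."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding="same", rng=None, bias: bool = True,
                 init: str = "glorot"):
        super().__init__()
        rng = _as_rng(rng)
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        w = (he_normal(rng, (c_out, c_in, kernel, kernel), fan_in)
             if init == "he"
             else glorot_uniform(rng, (c_out, c_in, kernel, kernel), fan_in, fan_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out, dtype=T.get_default_dtype())) if bias else None
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def _pads(self, h: int, w: int):
        if self.padding == "valid":
            return (0, 0), (0, 0)
        if self.padding == "same":
            return same_pads(h, self.kernel, self.stride), same_pads(w, self.kernel, self.stride)
        p = int(self.padding)
        return (p, p), (p, p)

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.stride,
                        self._pads(x.shape[2], x.shape[3]))


class ConvTranspose2d(Module):
    """Transposed convolution with Keras 'same' semantics: output = input*stride.

    Implemented as an ordinary convolution of the zero-dilated input with
    the spatially flipped kernel, then cropped.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1, rng=None):
        super().__init__()
        rng = _as_rng(rng)
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        # stored as (C_in, C_out, kh, kw), the conventional transposed layout
        self.weight = Parameter(
            glorot_uniform(rng, (c_in, c_out, kernel, kernel), fan_in, fan_out))
        self.bias = Parameter(np.zeros(c_out, dtype=T.get_default_dtype()))
        self.kernel, self.stride = kernel, stride

    def forward(self, x: Tensor) -> Tensor:
        k, s = self.kernel, self.stride
        h, w = x.shape[2], x.shape[3]
        xd = T.dilate2d(x, s)
        w_conv = T.flip_kernel_transpose(self.weight)
        full = T.conv2d(xd, w_conv, self.bias, 1, ((k - 1, k - 1), (k - 1, k - 1)))
        # crop the 'full' output down to size*stride, Keras-style
        target_h, target_w = h * s, w * s
        fh, fw = full.shape[2], full.shape[3]
        ct = (fh - target_h) // 2
        cl = (fw - target_w) // 2
        return T.crop2d(full, ((ct, fh - target_h - ct), (cl, fw - target_w - cl)))


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        dt = T.get_default_dtype()
        self.gamma = Parameter(np.ones(channels, dtype=dt))
        self.beta = Parameter(np.zeros(channels, dtype=dt))
        self.register_buffer("running_mean", np.zeros(channels, dtype=dt))
        self.register_buffer("running_var", np.ones(channels, dtype=dt))
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self._set_buffer("running_mean",
                             ((1 - m) * self.running_mean + m * mean).astype(mean.dtype))
            self._set_buffer("running_var",
                             ((1 - m) * self.running_var + m * var).astype(var.dtype))
            return T.batchnorm(x, self.gamma, self.beta, mean, var, self.eps,
                               (0, 2, 3), stats_from_batch=True)
        return T.batchnorm(x, self.gamma, self.beta, self.running_mean,
                           self.running_var, self.eps, (0, 2, 3),
                           stats_from_batch=False)


class Dropout(Module):
    """Inverted dropout with a module-owned random stream."""

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        self.p = p
        self.reseed(seed)

    def reseed(self, seed: int) -> None:
        object.__setattr__(self, "rng", np.random.default_rng(seed))

    def forward(self, x: Tensor) -> Tensor:
        return T.dropout(x, self.p, self.rng, self.training)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return T.maxpool2d(x, self.kernel, self.stride, self.padding)


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Upsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: Tensor) -> Tensor:
        data = x.data.repeat(2, axis=2).repeat(2, axis=3)
        out = Tensor(data, x.requires_grad, (x,))
        n, c, h, w = x.shape

        def _bw(g):
            if x.requires_grad:
                x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        out._backward = _bw
        return out
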