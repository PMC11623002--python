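"""Reverse-mode automatic differentiation on numpy arrays.

A define-by-run graph of :class:`Tensor` nodes, just large enough to train
the convolutional generator/discriminator pair and the split residual
classifier in this package: dense, embedding, (transposed) convolution,
batch normalization, pooling, dropout, the usual pointwise nonlinearities
and the two classification losses. Everything is float32 by default
(float64 is available for finite-difference gradient checking via
``set_default_dtype``).
"""

from __future__ import annotations

import numpy as np

_DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Set the dtype used for new tensors (float32 or float64)."""
    global _DEFAULT_DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DEFAULT_DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ info
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -------------------------------------------------------------- backward
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; accumulates into ``.grad`` leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)
        if grad.shape != self.data.shape:
            raise ValueError(
                f"gradient shape {grad.shape} does not match tensor shape {self.data.shape}"
            )
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = _bw
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        out._backward = _bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = _bw
        return out

    __matmul__ = matmul

    # -------------------------------------------------------------- shaping
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        out._backward = _bw
        return out

    def transpose(self, axes) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = _bw
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        shape = self.data.shape

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ pointwise
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = _bw
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mult = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype)
        out = Tensor(self.data * mult, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * mult)

        out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        x = self.data
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        out = Tensor(y, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = _bw
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = ((self.data >= lo) & (self.data <= hi)).astype(self.data.dtype)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = _bw
        return out


# ------------------------------------------------------------------ helpers
def concat(tensors: list[Tensor], axis: int) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out._backward = _bw
    return out


def pad2d(x: Tensor, pads) -> Tensor:
    """Zero-pad the two trailing axes of an NCHW tensor.

    ``pads`` is ((top, bottom), (left, right)).
    """
    (pt, pb), (pl, pr) = pads
    data = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    out = Tensor(data, x.requires_grad, (x,))
    h, w = x.data.shape[2], x.data.shape[3]

    def _bw(g):
        if x.requires_grad:
            x._accum(g[:, :, pt:pt + h, pl:pl + w])

    out._backward = _bw
    return out


def crop2d(x: Tensor, crops) -> Tensor:
    """Crop the two trailing axes; inverse of :func:`pad2d`."""
    (ct, cb), (cl, cr) = crops
    h, w = x.data.shape[2], x.data.shape[3]
    sl = (slice(None), slice(None), slice(ct, h - cb), slice(cl, w - cr))
    out = Tensor(x.data[sl], x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[sl] = g
            x._accum(full)

    out._backward = _bw
    return out


def dilate2d(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride-1`` zeros between spatial elements (for transposed conv)."""
    if stride == 1:
        return x
    n, c, h, w = x.data.shape
    data = np.zeros((n, c, (h - 1) * stride + 1, (w - 1) * stride + 1),
                    dtype=x.data.dtype)
    data[:, :, ::stride, ::stride] = x.data
    out = Tensor(data, x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(g[:, :, ::stride, ::stride])

    out._backward = _bw
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(N,C,H,W) padded input -> (N*Ho*Wo, C*kh*kw) patch matrix."""
    n, c, h, w = xp.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]           # (N, C, Ho, Wo, kh, kw)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(col), ho, wo


def _col2im(dcol: np.ndarray, xp_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, h, w = xp_shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    dcol = dcol.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros(xp_shape, dtype=dcol.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dcol[:, :, i, j]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int,
           padding) -> Tensor:
    """2-D convolution, NCHW; ``weight`` is (F, C, kh, kw).

    ``padding`` is ((top, bottom), (left, right)) — asymmetric pads cover
    Keras-style 'same' with even input sizes.
    """
    kh, kw = weight.data.shape[2], weight.data.shape[3]
    f = weight.data.shape[0]
    (pt, pb), (pl, pr) = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    col, ho, wo = _im2col(xp, kh, kw, stride)
    wmat = weight.data.reshape(f, -1).T          # (C*kh*kw, F)
    out_mat = col @ wmat
    if bias is not None:
        out_mat = out_mat + bias.data
    n = x.data.shape[0]
    out_data = out_mat.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)
    req = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, req, parents)
    xp_shape = xp.shape
    h, w = x.data.shape[2], x.data.shape[3]

    def _bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, f)
        if weight.requires_grad:
            dw = (col.T @ gmat).T.reshape(weight.data.shape)
            weight._accum(dw)
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcol = gmat @ wmat.T
            dxp = _col2im(dcol, xp_shape, kh, kw, stride)
            x._accum(dxp[:, :, pt:pt + h, pl:pl + w])

    out._backward = _bw
    return out


def flip_kernel_transpose(w: Tensor) -> Tensor:
    """(Cin, Cout, kh, kw) -> spatially flipped (Cout, Cin, kh, kw).

    Turns a transposed-convolution weight into an ordinary convolution
    weight over the zero-dilated input.
    """
    data = w.data[:, :, ::-1, ::-1].swapaxes(0, 1).copy()
    out = Tensor(data, w.requires_grad, (w,))

    def _bw(g):
        if w.requires_grad:
            w._accum(g.swapaxes(0, 1)[:, :, ::-1, ::-1])

    out._backward = _bw
    return out


def maxpool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    neg = np.finfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                constant_values=neg)
    n, c, h, w = xp.shape
    ho = (h - kernel) // stride + 1
    wo = (w - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride].reshape(n, c, ho, wo, kernel * kernel)
    arg = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, x.requires_grad, (x,))
    hin, win_ = x.data.shape[2], x.data.shape[3]

    def _bw(g):
        if not x.requires_grad:
            return
        dxp = np.zeros((n, c, h, w), dtype=g.dtype)
        ki, kj = np.divmod(arg, kernel)
        ii = (np.arange(ho) * stride)[None, None, :, None] + ki
        jj = (np.arange(wo) * stride)[None, None, None, :] + kj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn, cc, ii, jj), g)
        x._accum(dxp[:, :, padding:padding + hin, padding:padding + win_])

    out._backward = _bw
    return out


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(weight.data[idx], weight.requires_grad, (weight,))

    def _bw(g):
        if weight.requires_grad:
            dw = np.zeros_like(weight.data)
            np.add.at(dw, idx, g)
            weight._accum(dw)

    out._backward = _bw
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
              var: np.ndarray, eps: float, axes: tuple,
              stats_from_batch: bool = True) -> Tensor:
    """Normalize with the given statistics.

    With ``stats_from_batch`` the gradient treats mean/var as functions of
    ``x`` (training mode); otherwise they are constants (running stats).
    """
    shape = [1] * x.data.ndim
    c_axis = 1 if x.data.ndim == 4 else -1
    shape[c_axis] = x.data.shape[c_axis]
    shape = tuple(shape)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shape)) * invstd.reshape(shape)
    out_data = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    out = Tensor(out_data, x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))
    m = x.data.size // x.data.shape[c_axis]

    def _bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gs = g * gamma.data.reshape(shape)
            if stats_from_batch:
                dmean = gs.sum(axis=axes, keepdims=True)
                dproj = (gs * xhat).sum(axis=axes, keepdims=True)
                dx = (gs - dmean / m - xhat * dproj / m) * invstd.reshape(shape)
            else:
                dx = gs * invstd.reshape(shape)
            x._accum(dx)

    out._backward = _bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(keep)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean categorical cross-entropy over the batch.

    Returns (loss tensor, softmax probabilities as a numpy array).
    """
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    if labels.min() < 0 or labels.max() >= logits.data.shape[1]:
        raise ValueError("label out of range for the number of classes")
    eps = np.finfo(probs.dtype).tiny
    loss_val = -np.log(probs[np.arange(n), labels] + eps).mean()
    out = Tensor(loss_val, logits.requires_grad, (logits,))

    def _bw(g):
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(n), labels] -= 1.0
            logits._accum(g * d / n)

    out._backward = _bw
    return out, probs


def binary_cross_entropy(probs: Tensor, targets: np.ndarray,
                         eps: float = 1e-7) -> Tensor:
    """Mean BCE on probabilities (clipped away from 0/1)."""
    t = np.asarray(targets, dtype=probs.data.dtype).reshape(probs.data.shape)
    p = probs.clip(eps, 1.0 - eps)
    loss = -(Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log())
    return loss.mean()
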