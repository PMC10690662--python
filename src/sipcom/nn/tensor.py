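"""Minimal reverse-mode autodiff on numpy arrays.

Only the operations the translation model needs are implemented: 3D
convolution and transpose convolution, batch normalization, PReLU, channel
concatenation, elementwise arithmetic and the two losses (MSE,
binary cross-entropy on logits).  Arrays are float32; the graph is a tape of
backward closures released after ``backward()``.

Convolutions use the NCDHW layout.  im2col/col2im are written as loops over
the k^3 kernel offsets with strided slice assignment, which keeps them exact
(pure additions) and fast enough for patch-scale volumes without any
compiled extension.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "conv_transpose3d",
    "batch_norm",
    "prelu",
    "concat",
    "mse_loss",
    "bce_with_logits",
]

DTYPE = np.float32


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the tape as we go
            node._backward = None
            node._prev = ()

    # -- basic ops ------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data + other.data)
        out._prev = (self, other)

        def _bw(g):
            self._accumulate(g)
            other._accumulate(g)

        out._backward = _bw
        return out

    def __mul__(self, scalar: float) -> "Tensor":
        s = float(scalar)
        out = Tensor(self.data * s)
        out._prev = (self,)
        out._backward = lambda g: self._accumulate(g * s)
        return out

    __rmul__ = __mul__

    def mean(self) -> "Tensor":
        out = Tensor(self.data.mean())
        out._prev = (self,)
        n = self.data.size
        out._backward = lambda g: self._accumulate(
            np.full_like(self.data, float(g) / n)
        )
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data.astype(np.float64)))
        y = y.astype(DTYPE)
        out = Tensor(y)
        out._prev = (self,)
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out


# -- im2col / col2im ------------------------------------------------------


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def _im2col(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """(N, C, Dp, Hp, Wp) padded input -> (N, C, k, k, k, Do, Ho, Wo)."""
    n, c, dp, hp, wp = xp.shape
    do, ho, wo = (
        (dp - k) // s + 1,
        (hp - k) // s + 1,
        (wp - k) // s + 1,
    )
    cols = np.empty((n, c, k, k, k, do, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                cols[:, :, i, j, l] = xp[
                    :,
                    :,
                    i : i + s * do : s,
                    j : j + s * ho : s,
                    l : l + s * wo : s,
                ]
    return cols


def _col2im(
    cols: np.ndarray, spatial: tuple[int, int, int], k: int, s: int
) -> np.ndarray:
    """Adjoint of _im2col: scatter-add columns back onto the padded grid."""
    n, c = cols.shape[:2]
    do, ho, wo = cols.shape[-3:]
    out = np.zeros((n, c) + spatial, dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                out[
                    :,
                    :,
                    i : i + s * do : s,
                    j : j + s * ho : s,
                    l : l + s * wo : s,
                ] += cols[:, :, i, j, l]
    return out


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def _unpad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return x[:, :, p:-p, p:-p, p:-p]


# -- neural-net primitives -------------------------------------------------


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """3D cross-correlation.  x: (N, C, D, H, W); w: (O, C, k, k, k)."""
    k = w.data.shape[-1]
    xp = _pad(x.data, padding)
    cols = _im2col(xp, k, stride)  # (N, C, k,k,k, Do,Ho,Wo)
    n = x.data.shape[0]
    o = w.data.shape[0]
    spatial = cols.shape[-3:]
    cols2 = cols.reshape(n, -1, int(np.prod(spatial)))  # (N, C*k^3, L)
    w2 = w.data.reshape(o, -1)  # (O, C*k^3)
    y = np.einsum("ok,nkl->nol", w2, cols2, optimize=True)
    if b is not None:
        y = y + b.data[None, :, None]
    out = Tensor(y.reshape((n, o) + spatial))
    out._prev = tuple(t for t in (x, w, b) if t is not None)
    padded_shape = xp.shape[2:]

    def _bw(g):
        gl = g.reshape(n, o, -1)
        if b is not None:
            b._accumulate(gl.sum(axis=(0, 2)))
        w._accumulate(
            np.einsum("nol,nkl->ok", gl, cols2, optimize=True).reshape(w.data.shape)
        )
        dcols = np.einsum("ok,nol->nkl", w2, gl, optimize=True)
        dxp = _col2im(
            dcols.reshape((n, x.data.shape[1], k, k, k) + spatial),
            padded_shape,
            k,
            stride,
        )
        x._accumulate(_unpad(dxp, padding))

    out._backward = _bw
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2) -> Tensor:
    """3D transpose convolution (upsampling).  x: (N, C_in, D, H, W);
    w: (C_in, C_out, k, k, k); output spatial = stride*(in-1) + k."""
    n, cin = x.data.shape[:2]
    cout, k = w.data.shape[1], w.data.shape[-1]
    in_spatial = x.data.shape[2:]
    out_spatial = tuple(stride * (s - 1) + k for s in in_spatial)
    xl = x.data.reshape(n, cin, -1)  # (N, Cin, L)
    w2 = w.data.reshape(cin, -1)  # (Cin, Cout*k^3)
    cols = np.einsum("ck,ncl->nkl", w2, xl, optimize=True)
    y = _col2im(
        cols.reshape((n, cout, k, k, k) + in_spatial), out_spatial, k, stride
    )
    if b is not None:
        y = y + b.data[None, :, None, None, None]
    out = Tensor(y)
    out._prev = tuple(t for t in (x, w, b) if t is not None)

    def _bw(g):
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        gcols = _im2col(g, k, stride).reshape(n, -1, xl.shape[-1])  # (N, Cout*k^3, L)
        x._accumulate(
            np.einsum("ck,nkl->ncl", w2, gcols, optimize=True).reshape(x.data.shape)
        )
        w._accumulate(
            np.einsum("ncl,nkl->ck", xl, gcols, optimize=True).reshape(w.data.shape)
        )

    out._backward = _bw
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, D, H, W).

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the running buffers are used.
    """
    axes = (0, 2, 3, 4)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    shape = (1, -1, 1, 1, 1)
    xhat = (x.data - mean.reshape(shape)) * inv_std.reshape(shape)
    out = Tensor(gamma.data.reshape(shape) * xhat + beta.data.reshape(shape))
    out._prev = (x, gamma, beta)

    def _bw(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        gh = g * gamma.data.reshape(shape)
        if training:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3] * x.data.shape[4]
            dx = (
                gh
                - gh.mean(axis=axes, keepdims=True)
                - xhat * (gh * xhat).mean(axis=axes, keepdims=True)
            ) * inv_std.reshape(shape)
            del m
        else:
            dx = gh * inv_std.reshape(shape)
        x._accumulate(dx)

    out._backward = _bw
    return out


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """Parametric ReLU with one slope per channel (axis 1)."""
    shape = (1, -1, 1, 1, 1)
    a = alpha.data.reshape(shape)
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, a * x.data))
    out._prev = (x, alpha)

    def _bw(g):
        x._accumulate(np.where(pos, g, a * g))
        alpha._accumulate((g * np.where(pos, 0.0, x.data)).sum(axis=(0, 2, 3, 4)))

    out._backward = _bw
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    out = Tensor(np.concatenate([a.data, b.data], axis=1))
    out._prev = (a, b)
    ca = a.data.shape[1]

    def _bw(g):
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])

    out._backward = _bw
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    t = np.asarray(target, dtype=DTYPE)
    diff = pred.data - t
    out = Tensor(np.mean(diff**2))
    out._prev = (pred,)
    out._backward = lambda g: pred._accumulate(float(g) * 2.0 * diff / diff.size)
    return out


def bce_with_logits(logits: Tensor, target: float | np.ndarray) -> Tensor:
    """Numerically stable sigmoid + binary cross-entropy, mean-reduced."""
    x = logits.data.astype(np.float64)
    t = np.broadcast_to(np.asarray(target, dtype=np.float64), x.shape)
    # log(1 + e^x) computed stably
    loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(loss.mean())
    out._prev = (logits,)
    sig = 1.0 / (1.0 + np.exp(-x))

    def _bw(g):
        logits._accumulate((float(g) * (sig - t) / x.size).astype(DTYPE))

    out._backward = _bw
    return out
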