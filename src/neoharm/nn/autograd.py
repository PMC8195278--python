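"""Minimal reverse-mode automatic differentiation on numpy arrays.

This backend exists so the 3D segmentation / adversarial networks in this
package are real, trainable models on CPU with no external deep-learning
runtime.  It implements exactly the operations those architectures need:
elementwise arithmetic, reductions, matrix products, 3D convolution and
transposed convolution (via im2col / scatter-add), 2x2x2 pooling, instance
normalization, trilinear resampling, channel softmax and concatenation.

Gradients are accumulated by topological-order backpropagation from a scalar
loss.  All operations are deterministic.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            is_leaf = node._backward is None
            if not is_leaf and node.grad is not None:
                node._backward(node.grad)
            # release closures, graph links and intermediate grads as each
            # node retires: reference cycles through backward closures would
            # otherwise keep whole 3D activation graphs alive until a gc pass
            node._backward = None
            node._parents = ()
            if not is_leaf and node is not self:
                node.grad = None

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * Tensor._wrap(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._wrap(other) * self**-1.0

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        out._backward = bwd
        return out

    # -- reductions & elementwise functions ----------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out.data**2))
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data * (1.0 - out.data))
        return out

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.where(mask, 1.0, slope))
        return out

    def transpose(self, axes: tuple[int, ...]) -> "Tensor":
        out = Tensor(np.ascontiguousarray(self.data.transpose(axes)), parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accumulate(np.ascontiguousarray(g.transpose(inv)))
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def softmax(self, axis: int = 1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot))

        out._backward = bwd
        return out

    # -- spatial operations (N, C, D, H, W) -----------------------------
    def pad3d(self, p: int) -> "Tensor":
        if p == 0:
            return self
        pw = ((0, 0), (0, 0), (p, p), (p, p), (p, p))
        out = Tensor(np.pad(self.data, pw), parents=(self,))
        out._backward = lambda g: self._accumulate(g[:, :, p:-p, p:-p, p:-p])
        return out

    def pad3d_asym(self, pads: tuple[tuple[int, int], ...]) -> "Tensor":
        """Zero-pad spatial dims of (N, C, D, H, W); pads = 3 (before, after) pairs."""
        if all(a == 0 and b == 0 for a, b in pads):
            return self
        pw = ((0, 0), (0, 0)) + tuple(pads)
        out = Tensor(np.pad(self.data, pw), parents=(self,))
        sl = tuple(slice(a, s + a) for (a, _), s in zip(pads, self.data.shape[2:]))

        def bwd(g):
            self._accumulate(g[(slice(None), slice(None)) + sl])

        out._backward = bwd
        return out

    def conv3d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 1) -> "Tensor":
        """3D cross-correlation. weight: (C_out, C_in, k, k, k)."""
        return _conv3d(self, weight, bias, stride, padding)

    def conv_transpose3d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 2) -> "Tensor":
        """Transposed 3D convolution, kernel 3, doubling geometry.

        weight: (C_in, C_out, 3, 3, 3); output spatial size = stride * input.
        Adjoint of conv3d(kernel=3, stride=2, padding=1) on the doubled grid.
        """
        return _conv_transpose3d(self, weight, bias, stride)

    def avg_pool2(self) -> "Tensor":
        n, c, d, h, w = self.data.shape
        r = self.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = Tensor(r.mean(axis=(3, 5, 7)), parents=(self,))

        def bwd(g):
            gg = np.broadcast_to(
                g[:, :, :, None, :, None, :, None],
                (n, c, d // 2, 2, h // 2, 2, w // 2, 2),
            ) / 8.0
            self._accumulate(gg.reshape(self.data.shape))

        out._backward = bwd
        return out

    def max_pool2(self) -> "Tensor":
        n, c, d, h, w = self.data.shape
        r = self.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        r2 = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
        amax = r2.argmax(axis=-1)
        out = Tensor(np.take_along_axis(r2, amax[..., None], axis=-1)[..., 0],
                     parents=(self,))

        def bwd(g):
            gfull = np.zeros_like(r2)
            np.put_along_axis(gfull, amax[..., None], g[..., None], axis=-1)
            gfull = gfull.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            gfull = gfull.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(self.data.shape)
            self._accumulate(gfull)

        out._backward = bwd
        return out

    def instance_norm(self, eps: float = 1e-5) -> "Tensor":
        axes = (2, 3, 4)
        mu = self.data.mean(axis=axes, keepdims=True)
        var = self.data.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = (self.data - mu) * inv
        out = Tensor(y, parents=(self,))

        def bwd(g):
            gm = g.mean(axis=axes, keepdims=True)
            gym = (g * y).mean(axis=axes, keepdims=True)
            self._accumulate(inv * (g - gm - y * gym))

        out._backward = bwd
        return out

    def resize_trilinear(self, out_shape: tuple[int, int, int]) -> "Tensor":
        """Separable trilinear resampling of (N, C, D, H, W) spatial dims."""
        mats = [
            _interp_matrix(self.data.shape[2 + i], out_shape[i], self.data.dtype)
            for i in range(3)
        ]
        y = self.data
        for i, a in enumerate(mats):
            y = np.moveaxis(np.tensordot(a, y, axes=([1], [2 + i])), 0, 2 + i)
        out = Tensor(np.ascontiguousarray(y), parents=(self,))

        def bwd(g):
            for i, a in enumerate(mats):
                g = np.moveaxis(np.tensordot(a.T, g, axes=([1], [2 + i])), 0, 2 + i)
            self._accumulate(np.ascontiguousarray(g))

        out._backward = bwd
        return out


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), parents=ts)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# convolution internals
# ---------------------------------------------------------------------------

_COL_INDEX_CACHE: dict[tuple, np.ndarray] = {}


def _col_indices(cshape: tuple[int, int, int, int], k: int, s: int) -> np.ndarray:
    """Flat indices into a padded (C, D, H, W) array for each im2col element."""
    key = (cshape, k, s)
    idx = _COL_INDEX_CACHE.get(key)
    if idx is None:
        base = np.arange(int(np.prod(cshape)), dtype=np.int64).reshape(cshape)
        win = sliding_window_view(base, (k, k, k), axis=(1, 2, 3))[:, ::s, ::s, ::s]
        c, do, ho, wo = win.shape[:4]
        idx = np.ascontiguousarray(
            win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(do * ho * wo, c * k**3)
        )
        _COL_INDEX_CACHE[key] = idx
    return idx


def _im2col(xp: np.ndarray, k: int, s: int) -> tuple[np.ndarray, tuple[int, int, int]]:
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))[:, ::s, ::s, ::s]
    c, do, ho, wo = win.shape[:4]
    cols = np.ascontiguousarray(
        win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(do * ho * wo, c * k**3)
    )
    return cols, (do, ho, wo)


def _col2im(cols: np.ndarray, cshape: tuple[int, int, int, int], k: int, s: int) -> np.ndarray:
    idx = _col_indices(cshape, k, s)
    flat = np.bincount(idx.ravel(), weights=cols.astype(np.float64).ravel(),
                       minlength=int(np.prod(cshape)))
    return flat.reshape(cshape)


def _use_correlate(stride: int, k: int, padding: int, c_in: int, c_out: int,
                   n_vox: int) -> bool:
    """Fast path: scipy per-pair correlation beats im2col for big grids with
    few channels (no column materialization)."""
    return (stride == 1 and k == 3 and padding == 1
            and n_vox >= 4096 and c_in * c_out <= 256)


def _cols_channel_major(xp: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """(C, 27, L) column tensor for a padded (C, D+2, H+2, W+2) array.

    Built from 27 strided slice copies (no 7-D transpose gather), feeding a
    single GEMM against the (C_out, C*27) weight matrix.
    """
    c = xp.shape[0]
    d, h, w = shape
    cols = np.empty((c, 27, d * h * w), dtype=xp.dtype)
    i = 0
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                cols[:, i] = xp[:, dz:dz + d, dy:dy + h, dx:dx + w].reshape(c, -1)
                i += 1
    return cols


def _conv3d_gemm(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Stride-1 3^3 'same' convolution via channel-major im2col + GEMM."""
    n, c_in = x.data.shape[0], x.data.shape[1]
    c_out = weight.data.shape[0]
    shape = x.data.shape[2:]
    L = int(np.prod(shape))
    w2 = weight.data.reshape(c_out, c_in * 27)
    y = np.empty((n, c_out) + shape, dtype=np.result_type(x.data, weight.data))
    for i in range(n):
        xp = np.pad(x.data[i], ((0, 0), (1, 1), (1, 1), (1, 1)))
        cols = _cols_channel_major(xp, shape)
        y[i] = (w2 @ cols.reshape(c_in * 27, L)).reshape((c_out,) + shape)
    if bias is not None:
        y = y + bias.data.reshape(1, -1, 1, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(y, parents=parents)

    def bwd(g):
        # columns are recomputed here rather than cached at forward time:
        # a cached column tensor per conv would hold O(27 C L) floats alive
        # across the whole graph and exhausts memory on 3D volumes
        if weight.requires_grad:
            gw = np.zeros((c_out, c_in * 27), dtype=np.float64)
            for i in range(n):
                xp = np.pad(x.data[i], ((0, 0), (1, 1), (1, 1), (1, 1)))
                cols = _cols_channel_major(xp, shape)
                gw += g[i].reshape(c_out, L) @ cols.reshape(c_in * 27, L).T
            weight._accumulate(gw.reshape(weight.data.shape).astype(weight.data.dtype))
        if x.requires_grad:
            # input grad = 'same' correlation of g with the flipped kernel
            wf = np.ascontiguousarray(
                weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            ).reshape(c_in, c_out * 27)
            gx = np.empty_like(x.data)
            for i in range(n):
                gp = np.pad(g[i], ((0, 0), (1, 1), (1, 1), (1, 1)))
                gcols = _cols_channel_major(gp, shape)
                gx[i] = (wf @ gcols.reshape(c_out * 27, L)).reshape((c_in,) + shape)
            x._accumulate(gx)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))

    out._backward = bwd
    return out


def _conv3d_correlate(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    from scipy import ndimage as _ndi

    n, c_in = x.data.shape[0], x.data.shape[1]
    c_out = weight.data.shape[0]
    y = np.empty((n, c_out) + x.data.shape[2:],
                 dtype=np.result_type(x.data, weight.data))
    for i in range(n):
        for o in range(c_out):
            acc = _ndi.correlate(x.data[i, 0], weight.data[o, 0], mode="constant")
            for c in range(1, c_in):
                acc += _ndi.correlate(x.data[i, c], weight.data[o, c],
                                      mode="constant")
            y[i, o] = acc
    if bias is not None:
        y = y + bias.data.reshape(1, -1, 1, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(y, parents=parents)

    def bwd(g):
        if x.requires_grad:
            gx = np.empty_like(x.data)
            for i in range(n):
                for c in range(c_in):
                    acc = _ndi.convolve(g[i, 0], weight.data[0, c], mode="constant")
                    for o in range(1, c_out):
                        acc += _ndi.convolve(g[i, o], weight.data[o, c],
                                             mode="constant")
                    gx[i, c] = acc
            x._accumulate(gx)
        if weight.requires_grad:
            gw = np.zeros(weight.data.shape, dtype=np.float64)
            for i in range(n):
                xp = np.pad(x.data[i], ((0, 0), (1, 1), (1, 1), (1, 1)))
                gi = g[i].reshape(c_out, -1)
                d, h, w = x.data.shape[2:]
                for dz in range(3):
                    for dy in range(3):
                        for dx in range(3):
                            v = xp[:, dz:dz + d, dy:dy + h, dx:dx + w]
                            gw[:, :, dz, dy, dx] += gi @ v.reshape(c_in, -1).T
            weight._accumulate(gw.astype(weight.data.dtype))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))

    out._backward = bwd
    return out


def _conv3d(x: Tensor, weight: Tensor, bias: Tensor | None,
            stride: int, padding: int) -> Tensor:
    n, c_in, d, h, w = x.data.shape
    c_out, c_in_w, k = weight.data.shape[0], weight.data.shape[1], weight.data.shape[2]
    if c_in != c_in_w:
        raise ValueError(f"conv3d channel mismatch: input {c_in}, weight {c_in_w}")
    n_vox = int(np.prod(x.data.shape[2:]))
    if stride == 1 and k == 3 and padding == 1 and n_vox >= 512:
        if c_in * c_out <= 16:
            return _conv3d_correlate(x, weight, bias)
        return _conv3d_gemm(x, weight, bias)
    p = padding
    w2 = weight.data.reshape(c_out, -1).T  # (C_in k^3, C_out)
    outs, pad_shapes = [], []
    for i in range(n):
        xp = np.pad(x.data[i], ((0, 0), (p, p), (p, p), (p, p))) if p else x.data[i]
        cols, oshape = _im2col(xp, k, stride)
        pad_shapes.append(xp.shape)
        y = cols @ w2
        outs.append(y.T.reshape(c_out, *oshape))
    ydata = np.stack(outs)
    if bias is not None:
        ydata = ydata + bias.data.reshape(1, -1, 1, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(ydata, parents=parents)

    def bwd(g):
        gw = np.zeros_like(weight.data, dtype=np.float64) if weight.requires_grad else None
        gx_all = np.zeros_like(x.data) if x.requires_grad else None
        if x.requires_grad and stride == 1:
            # full correlation with the flipped kernel (fast matmul path)
            wf = np.ascontiguousarray(
                weight.data[:, :, ::-1, ::-1, ::-1].transpose(0, 2, 3, 4, 1)
            ).reshape(-1, c_in)
        for i in range(n):
            cshape = pad_shapes[i]
            xp = (np.pad(x.data[i], ((0, 0), (p, p), (p, p), (p, p)))
                  if p else x.data[i])
            cols, _ = _im2col(xp, k, stride)
            gflat = np.ascontiguousarray(g[i].reshape(c_out, -1).T)  # (L, C_out)
            if weight.requires_grad:
                gw += (gflat.T @ cols).reshape(weight.data.shape)
            if x.requires_grad:
                if stride == 1:
                    q = k - 1 - p
                    gp = np.pad(g[i], ((0, 0), (q, q), (q, q), (q, q))) if q else g[i]
                    gcols, _ = _im2col(gp, k, 1)
                    gx_all[i] = (gcols @ wf).T.reshape(x.data.shape[1:])
                else:
                    gcols = gflat @ w2.T
                    gx = _col2im(gcols, cshape, k, stride)
                    if p:
                        gx = gx[:, p:-p, p:-p, p:-p]
                    gx_all[i] = gx
        if gx_all is not None:
            x._accumulate(gx_all)
        if gw is not None:
            weight._accumulate(gw.astype(weight.data.dtype))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))

    out._backward = bwd
    return out


def _conv_transpose3d(x: Tensor, weight: Tensor, bias: Tensor | None,
                      stride: int) -> Tensor:
    # Adjoint of conv3d(kernel=3, stride, padding=1) applied on the upsampled grid.
    n, c_in, d, h, w = x.data.shape
    c_in_w, c_out, k = weight.data.shape[0], weight.data.shape[1], weight.data.shape[2]
    if c_in != c_in_w:
        raise ValueError(f"conv_transpose3d channel mismatch: {c_in} vs {c_in_w}")
    p = 1
    od, oh, ow = stride * d, stride * h, stride * w
    cshape = (c_out, od + 2 * p, oh + 2 * p, ow + 2 * p)
    # scatter layout expects (L, C_out * k^3) ordered channel-major within window
    wmat = weight.data.transpose(1, 2, 3, 4, 0).reshape(-1, c_in)  # (C_out k^3, C_in)
    outs = []
    for i in range(n):
        xflat = x.data[i].reshape(c_in, -1).T  # (L, C_in)
        scat = _col2im(xflat @ wmat.T, cshape, k, stride)
        outs.append(scat[:, p:-p, p:-p, p:-p])
    ydata = np.stack(outs).astype(x.data.dtype)
    if bias is not None:
        ydata = ydata + bias.data.reshape(1, -1, 1, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(ydata, parents=parents)

    def bwd(g):
        gw = np.zeros((c_out * k**3, c_in)) if weight.requires_grad else None
        gx_all = np.zeros_like(x.data) if x.requires_grad else None
        for i in range(n):
            gp = np.pad(g[i], ((0, 0), (p, p), (p, p), (p, p)))
            cols, _ = _im2col(gp, k, stride)  # (L, C_out k^3)
            xflat = x.data[i].reshape(c_in, -1).T
            if weight.requires_grad:
                gw += cols.T @ xflat
            if x.requires_grad:
                gx_all[i] = (cols @ wmat).T.reshape(x.data.shape[1:])
        if gx_all is not None:
            x._accumulate(gx_all)
        if gw is not None:
            weight._accumulate(
                gw.reshape(c_out, k, k, k, c_in).transpose(4, 0, 1, 2, 3).astype(weight.data.dtype)
            )
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))

    out._backward = bwd
    return out


_INTERP_CACHE: dict[tuple, np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Linear interpolation matrix (n_out, n_in), half-pixel-centred."""
    key = (n_in, n_out, np.dtype(dtype).str)
    a = _INTERP_CACHE.get(key)
    if a is None:
        if n_in == n_out:
            a = np.eye(n_in, dtype=dtype)
        else:
            src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
            src = np.clip(src, 0, n_in - 1)
            lo = np.floor(src).astype(int)
            hi = np.minimum(lo + 1, n_in - 1)
            t = src - lo
            a = np.zeros((n_out, n_in), dtype=dtype)
            a[np.arange(n_out), lo] += (1 - t).astype(dtype)
            a[np.arange(n_out), hi] += t.astype(dtype)
        _INTERP_CACHE[key] = a
    return a
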