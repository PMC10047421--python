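"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations needed by the segmentation network are implemented:
elementwise arithmetic with broadcasting, log/sigmoid/relu/clip, axis
reductions, reshape/slice/concat, matmul, and fused CNN primitives
(2D convolution with stride/dilation, non-overlapping transposed
convolution, 2x2 max pooling, batch normalization).  Gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # keep NumPy from broadcasting Tensor operands elementwise; reflected
    # operators below handle ndarray <op> Tensor instead
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._result(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

        return Tensor._result(self.data - other.data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._result(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor._result(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def log(self):
        def backward(g):
            return (g / self.data,)

        return Tensor._result(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._result(out_data, (self,), lambda g: (g * out_data,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._result(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._result(
            np.where(mask, self.data, 0.0), (self,), lambda g: (g * mask,)
        )

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._result(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).astype(np.float32),)

        return Tensor._result(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            return (g.reshape(self.shape),)

        return Tensor._result(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._result(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros(self.shape, dtype=np.float32)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._result(self.data[idx], (self,), backward)

    # -- backward pass --------------------------------------------------------
    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)

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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad and g is not None:
                    parent._accumulate(g)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def concat(tensors, axis: int) -> Tensor:
    """Concatenate tensors along `axis` with gradient support."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


# -- fused CNN primitives -----------------------------------------------------


def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride=1, dilation=1,
           padding=0) -> Tensor:
    """2D cross-correlation over NCHW input with stride/dilation/zero-padding."""
    sh, sw = _pair(stride)
    dh, dw = _pair(dilation)
    ph, pw = _pair(padding)
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs weight {cin_w}")
    eh, ew = (kh - 1) * dh + 1, (kw - 1) * dw + 1  # effective kernel extent
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    hp, wp = xp.shape[2:]
    oh, ow = (hp - eh) // sh + 1, (wp - ew) // sw + 1

    view = np.lib.stride_tricks.sliding_window_view(xp, (eh, ew), axis=(2, 3))
    view = view[:, :, ::sh, ::sw, ::dh, ::dw]  # (n,cin,oh,ow,kh,kw)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, oh * ow, cin * kh * kw
    )
    w2 = weight.data.reshape(cout, cin * kh * kw)
    out = cols @ w2.T  # (n, oh*ow, cout)
    if bias is not None:
        out += bias.data
    out = out.transpose(0, 2, 1).reshape(n, cout, oh, ow)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gflat = g.transpose(0, 2, 3, 1).reshape(n, oh * ow, cout)
        gw = np.einsum("nlc,nlk->ck", gflat, cols).reshape(weight.shape)
        gcols = gflat @ w2  # (n, oh*ow, cin*kh*kw)
        gcols = gcols.reshape(n, oh, ow, cin, kh, kw).transpose(0, 3, 4, 5, 1, 2)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i * dh:i * dh + oh * sh:sh,
                    j * dw:j * dw + ow * sw:sw] += gcols[:, :, i, j]
        gx = gxp[:, :, ph:hp - ph, pw:wp - pw] if (ph or pw) else gxp
        if bias is None:
            return gx, gw
        gb = gflat.sum(axis=(0, 1))
        return gx, gw, gb

    return Tensor._result(out, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride (non-overlapping upsample).

    weight shape: (cin, cout, k, k); output spatial size = input * k.
    """
    k = stride
    n, cin, h, w = x.shape
    cin_w, cout = weight.shape[:2]
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs weight {cin_w}")
    # (n,h,w,cout,k,k) -> (n,cout,h,k,w,k)
    out = np.tensordot(x.data, weight.data, axes=([1], [0]))
    out = out.transpose(0, 3, 1, 4, 2, 5).reshape(n, cout, h * k, w * k)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gb_blocks = g.reshape(n, cout, h, k, w, k).transpose(0, 2, 4, 1, 3, 5)
        # gb_blocks: (n,h,w,cout,k,k)
        gx = np.tensordot(gb_blocks, weight.data, axes=([3, 4, 5], [1, 2, 3]))
        gx = gx.transpose(0, 3, 1, 2)
        gw = np.tensordot(x.data, gb_blocks, axes=([0, 2, 3], [0, 1, 2]))
        if bias is None:
            return gx, gw
        gb = g.sum(axis=(0, 2, 3))
        return gx, gw, gb

    return Tensor._result(out, parents, backward)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial size ({h},{w}) not divisible by 2")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    blocks = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gb = gb.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gb.reshape(n, c, h, w),)

    return Tensor._result(out, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
                 running_var, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N,H,W) per channel; updates running stats."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        # unbiased variance in the running estimate, as is conventional
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mean, var = running_mean, running_var

    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        m = g.shape[0] * g.shape[2] * g.shape[3]
        gg = (g * xhat).sum(axis=(0, 2, 3))
        gb = g.sum(axis=(0, 2, 3))
        if training:
            gx = (gamma.data * inv_std)[None, :, None, None] / m * (
                m * g
                - gb[None, :, None, None]
                - xhat * gg[None, :, None, None]
            )
        else:
            gx = g * (gamma.data * inv_std)[None, :, None, None]
        return gx.astype(np.float32), gg, gb

    return Tensor._result(out, (x, gamma, beta), backward)
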