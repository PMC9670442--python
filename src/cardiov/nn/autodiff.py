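"""Reverse-mode automatic differentiation on NumPy arrays.

A compact tape-based engine sufficient for 1D convolutional networks:
tensors record the operations that produced them, and :meth:`Tensor.backward`
walks the tape in reverse topological order accumulating gradients.

Only the primitives the network needs are provided; everything else
(batch norm, swish, softmax cross-entropy, SE gates) is composed from them,
so a finite-difference check of the primitives covers the whole model.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "sigmoid",
    "relu",
    "swish",
    "log",
    "exp",
    "sqrt",
    "softplus",
    "conv1d",
    "max_pool1d",
    "batch_norm_train",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self._grad_owned = False

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction helpers ------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=parents if req else (),
                      backward=backward if req else None)

    def _accum(self, g: np.ndarray):
        # First contribution: hold a reference (no zero-fill, no copy).
        # Gradients produced upstream are never mutated afterwards, and
        # in-place accumulation happens only once this node owns its buffer.
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    # -- arithmetic ------------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        """Batched matrix product with NumPy broadcasting semantics."""
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- reductions / shaping ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src_shape = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(src_shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- backprop ----------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: the net is ~200 nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- pointwise nonlinearities ------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return Tensor._make(s, (x,), backward)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def swish(x: Tensor) -> Tensor:
    """x * sigmoid(x) — the network's activation throughout (fused)."""
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = x.data * s

    def backward(g):
        if x.requires_grad:
            d = 1.0 - s          # d/dx = s * (1 + x * (1 - s)), built in place
            d *= x.data
            d += 1.0
            d *= s
            d *= g
            x._accum(d)

    return Tensor._make(out, (x,), backward)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)

    def backward(g):
        if x.requires_grad:
            x._accum(g / x.data)

    return Tensor._make(np.log(x.data), (x,), backward)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * out)

    return Tensor._make(out, (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    return x ** 0.5


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), computed stably; d/dx = sigmoid(x)."""
    x = as_tensor(x)
    out = np.logaddexp(0.0, x.data)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g):
        if x.requires_grad:
            x._accum(g * s)

    return Tensor._make(out, (x,), backward)


# -- structured primitives -----------------------------------------------------

def conv1d(x: Tensor, w: Tensor, stride: int = 1,
           pad_left: int = 0, pad_right: int = 0, groups: int = 1) -> Tensor:
    """Grouped 1D cross-correlation.

    x: (N, Cin, L); w: (Cout, Cin // groups, K) -> (N, Cout, Lout) with
    Lout = floor((L + pad_left + pad_right - K) / stride) + 1.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    N, Cin, L = x.shape
    Cout, cin_g, K = w.shape
    G = groups
    if Cin % G or Cout % G or cin_g != Cin // G:
        raise ValueError(
            f"channel counts ({Cin}->{Cout}) not compatible with {G} groups")

    if K == 1 and stride == 1 and pad_left == 0 and pad_right == 0 and G == 1:
        # pointwise convolution: a single (broadcast) matmul per direction
        w2 = w.data[:, :, 0]
        out = np.matmul(w2, x.data)

        def backward_pw(g):
            if w.requires_grad:
                gw = np.matmul(g, np.swapaxes(x.data, -1, -2)).sum(axis=0)
                w._accum(np.ascontiguousarray(gw[:, :, None]))
            if x.requires_grad:
                x._accum(np.matmul(w2.T, g))

        return Tensor._make(out, (x, w), backward_pw)

    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_left, pad_right)))
    Lp = xp.shape[-1]
    Lout = (Lp - K) // stride + 1
    if Lout <= 0:
        raise ValueError(f"input length {L} too short for kernel {K}")
    # accumulate over kernel taps: one grouped pointwise product per tap,
    # avoiding the (N, Cin, K, Lout) patch materialization
    xg = xp.reshape(N, G, cin_g, Lp)
    w_g = w.data.reshape(G, Cout // G, cin_g, K)
    out = np.zeros((N, G, Cout // G, Lout), dtype=xp.dtype)
    for k in range(K):
        sl = xg[:, :, :, k:k + stride * Lout:stride]
        out += np.matmul(w_g[:, :, :, k], sl)  # (G,O,C)@(N,G,C,L)->(N,G,O,L)
    out = out.reshape(N, Cout, Lout)

    def backward(g):
        g_g = g.reshape(N, G, Cout // G, Lout)
        if w.requires_grad:
            gw = np.empty_like(w_g)
            for k in range(K):
                sl = xg[:, :, :, k:k + stride * Lout:stride]
                gw[:, :, :, k] = np.matmul(
                    g_g, np.swapaxes(sl, -1, -2)).sum(axis=0)
            w._accum(gw.reshape(Cout, cin_g, K))
        if x.requires_grad:
            gxp = np.zeros_like(xp).reshape(N, G, cin_g, Lp)
            wt = np.swapaxes(w_g, 1, 2)  # (G, C, O, K)
            for k in range(K):
                gxp[:, :, :, k:k + stride * Lout:stride] += np.matmul(
                    wt[:, :, :, k], g_g)
            gxp = gxp.reshape(N, Cin, Lp)
            x._accum(gxp[:, :, pad_left:Lp - pad_right if pad_right else None])

    return Tensor._make(out, (x, w), backward)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                     eps: float = 1e-5):
    """Fused training-mode batch normalization over (batch[, time]).

    x: (N, C, L) or (N, C); gamma, beta: (C,). Returns
    (out, batch_mean, batch_var) where the statistics are plain (C,) arrays
    for running-estimate updates.
    """
    x = as_tensor(x)
    gamma = as_tensor(gamma)
    beta = as_tensor(beta)
    axes = (0, 2) if x.ndim == 3 else (0,)
    cshape = (1, -1, 1) if x.ndim == 3 else (1, -1)
    m = int(np.prod([x.shape[a] for a in axes]))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    gc = gamma.data.reshape(cshape)
    out = xhat * gc + beta.data.reshape(cshape)

    def backward(g):
        if gamma.requires_grad:
            spec = "ncl,ncl->c" if g.ndim == 3 else "nc,nc->c"
            gamma._accum(np.einsum(spec, g, xhat))  # no (N,C,L) temporary
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gc
            t1 = dxhat.sum(axis=axes, keepdims=True)
            t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
            # dx = ivar/m * (m*dxhat - t1 - xhat*t2), assembled in place
            dxhat -= t1 / m
            t2 *= 1.0 / m
            dxhat -= xhat * t2
            dxhat *= ivar
            x._accum(dxhat)

    out_t = Tensor._make(out, (x, gamma, beta), backward)
    return out_t, mu.reshape(-1), var.reshape(-1)


def max_pool1d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    """1D max pooling; trailing samples that do not fill a window are dropped."""
    x = as_tensor(x)
    N, C, L = x.shape
    Lout = (L - kernel) // stride + 1
    windows = np.empty((N, C, Lout, kernel), dtype=x.data.dtype)
    for k in range(kernel):
        windows[..., k] = x.data[:, :, k:k + stride * Lout:stride]
    arg = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        # positions of each window's max in the input
        base = np.arange(Lout) * stride
        pos = base[None, None, :] + arg  # (N, C, Lout)
        n_idx = np.arange(N)[:, None, None]
        c_idx = np.arange(C)[None, :, None]
        np.add.at(gx, (n_idx, c_idx, pos), g)
        x._accum(gx)

    return Tensor._make(out, (x,), backward)
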