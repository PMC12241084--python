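"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the segmentation network: a ``Tensor``
wrapping an ``ndarray`` plus the handful of differentiable operations the
architecture needs (elementwise arithmetic, reductions, concatenation,
2-D convolution via im2col, zero-insertion for transposed convolution,
separable bilinear upsampling, dropout). Gradients are accumulated by a
topological-order sweep from a scalar loss.

Convolution gathers patches with fancy indexing and scatters gradients back
through a cached ``scipy.sparse`` col2im matrix, which keeps the backward
pass vectorised on a single CPU.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "neg", "power", "exp", "log", "sqrt",
    "relu", "prelu", "sigmoid", "clip",
    "tsum", "tmean", "concat", "broadcast_to", "take_item",
    "conv2d", "zero_insert", "flip_kernel", "bilinear_upsample", "dropout",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this node.

        ``grad`` defaults to 1 and therefore requires a scalar output.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient needs a scalar")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            taken: set[int] = set()  # arrays adopted without copy this call
            for parent, pgrad in node._backward(node.grad):
                if not (parent.requires_grad or parent._parents):
                    continue
                if parent.grad is None:
                    if (pgrad.dtype == parent.data.dtype and pgrad.flags.owndata
                            and pgrad is not node.grad and id(pgrad) not in taken):
                        parent.grad = pgrad
                        taken.add(id(pgrad))
                    else:
                        parent.grad = pgrad.astype(parent.data.dtype)
                else:
                    parent.grad += pgrad

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nextra = grad.ndim - len(shape)
    if nextra:
        grad = grad.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data + b.data, (a, b),
                 lambda g: ((a, _unbroadcast(g, a.data.shape)),
                            (b, _unbroadcast(g, b.data.shape))))


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data - b.data, (a, b),
                 lambda g: ((a, _unbroadcast(g, a.data.shape)),
                            (b, _unbroadcast(-g, b.data.shape))))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data * b.data, (a, b),
                 lambda g: ((a, _unbroadcast(g * b.data, a.data.shape)),
                            (b, _unbroadcast(g * a.data, b.data.shape))))


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data / b.data, (a, b),
                 lambda g: ((a, _unbroadcast(g / b.data, a.data.shape)),
                            (b, _unbroadcast(-g * a.data / b.data ** 2, b.data.shape))))


def neg(a: Tensor) -> Tensor:
    return _node(-a.data, (a,), lambda g: ((a, -g),))


def power(a: Tensor, p: float) -> Tensor:
    return _node(a.data ** p, (a,),
                 lambda g: ((a, g * p * a.data ** (p - 1)),))


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    return _node(out_data, (a,), lambda g: ((a, g * out_data),))


def log(a: Tensor) -> Tensor:
    return _node(np.log(a.data), (a,), lambda g: ((a, g / a.data),))


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)
    return _node(out_data, (a,), lambda g: ((a, g * 0.5 / out_data),))


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only inside the interval."""
    mask = (a.data > lo) & (a.data < hi)
    return _node(np.clip(a.data, lo, hi), (a,),
                 lambda g: ((a, g * mask),))


# ---------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _node(a.data * mask, (a,), lambda g: ((a, g * mask),))


def prelu(a: Tensor, alpha: Tensor) -> Tensor:
    """Per-channel parametric ReLU; ``alpha`` has shape (C,) against NCHW."""
    al = alpha.data.reshape(1, -1, 1, 1) if a.data.ndim == 4 else alpha.data
    pos = a.data > 0
    out_data = np.where(pos, a.data, al * a.data)

    def backward(g):
        ga = np.where(pos, g, al * g)
        galpha = np.where(pos, 0.0, g * a.data)
        if a.data.ndim == 4:
            galpha = galpha.sum(axis=(0, 2, 3))
        return ((a, ga), (alpha, galpha.reshape(alpha.data.shape)))

    return _node(out_data, (a, alpha), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-branch form
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return _node(out_data, (a,),
                 lambda g: ((a, g * out_data * (1.0 - out_data)),))


# ---------------------------------------------------------------------
# reductions / shaping
# ---------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return ((a, np.broadcast_to(g, a.data.shape).copy()),)
        gx = g
        if not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            for d in sorted(ax):
                gx = np.expand_dims(gx, d)
        return ((a, np.broadcast_to(gx, a.data.shape).copy()),)

    return _node(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[d] for d in (axis if isinstance(axis, tuple) else (axis,))])
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    return _node(np.broadcast_to(a.data, shape).copy(), (a,),
                 lambda g: ((a, _unbroadcast(g, a.data.shape)),))


def take_item(a: Tensor, index: int, axis: int = 0) -> Tensor:
    """Select one index along ``axis`` (used to split a batch into the
    per-slice loss terms)."""
    out_data = np.take(a.data, index, axis=axis)

    def backward(g):
        gx = np.zeros_like(a.data)
        sl = [slice(None)] * a.data.ndim
        sl[axis] = index
        gx[tuple(sl)] = g
        return ((a, gx),)

    return _node(out_data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for t, s0, s1 in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(s0, s1)
            grads.append((t, g[tuple(idx)]))
        return tuple(grads)

    return _node(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------
# convolution machinery
# ---------------------------------------------------------------------

_COL2IM_CACHE: dict = {}


def _conv_geometry(Hp, Wp, KH, KW, stride, dilation):
    OH = (Hp - ((KH - 1) * dilation + 1)) // stride + 1
    OW = (Wp - ((KW - 1) * dilation + 1)) // stride + 1
    idx_h = (np.arange(OH)[:, None] * stride + np.arange(KH)[None, :] * dilation)
    idx_w = (np.arange(OW)[:, None] * stride + np.arange(KW)[None, :] * dilation)
    return OH, OW, idx_h, idx_w


def _col2im_matrix(Hp, Wp, KH, KW, stride, dilation):
    """Sparse (Hp*Wp, OH*OW*KH*KW) scatter matrix for the conv backward."""
    key = (Hp, Wp, KH, KW, stride, dilation)
    mat = _COL2IM_CACHE.get(key)
    if mat is None:
        OH, OW, idx_h, idx_w = _conv_geometry(Hp, Wp, KH, KW, stride, dilation)
        # flat index of each (oh, ow, kh, kw) patch element in the padded image
        flat = (idx_h[:, None, :, None] * Wp + idx_w[None, :, None, :]).ravel()
        n = flat.size
        mat = sp.csr_matrix(
            (np.ones(n, dtype=np.float32), (flat, np.arange(n))),
            shape=(Hp * Wp, n))
        _COL2IM_CACHE[key] = mat
    return mat


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW input, OIHW weight.

    Internally gathers patches channels-last so the heavy lifting is a
    single BLAS matmul in each direction.
    """
    N, C, H, W = x.data.shape
    O, Ci, KH, KW = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2:]
    OH, OW, idx_h, idx_w = _conv_geometry(Hp, Wp, KH, KW, stride, dilation)
    if OH <= 0 or OW <= 0:
        raise ValueError("conv2d: spatial dims too small for kernel/dilation")
    # channels-last gather -> contiguous (N*OH*OW, KH*KW*C) column matrix
    xpT = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))
    patches = xpT[:, idx_h[:, None, :, None], idx_w[None, :, None, :], :]
    K = KH * KW * C
    cols = patches.reshape(N * OH * OW, K)
    wmat = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0)).reshape(K, O)
    y = cols @ wmat
    out_data = np.ascontiguousarray(
        y.reshape(N, OH, OW, O).transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        grads = []
        gyT = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * OH * OW, O)
        gwmat = cols.T @ gyT  # (K, O)
        grads.append((w, np.ascontiguousarray(
            gwmat.reshape(KH, KW, C, O).transpose(3, 2, 0, 1))))
        if b is not None:
            grads.append((b, gyT.sum(axis=0)))
        gcols = gyT @ wmat.T  # (N*OH*OW, K)
        mat = _col2im_matrix(Hp, Wp, KH, KW, stride, dilation)
        # scatter per item: (Hp*Wp, OH*OW*KH*KW) @ (OH*OW*KH*KW, C)
        gk = gcols.reshape(N, OH * OW * KH * KW, C)
        gxpT = np.empty((N, Hp * Wp, C), dtype=g.dtype)
        for i in range(N):
            gxpT[i] = mat @ gk[i]
        gxp = gxpT.reshape(N, Hp, Wp, C).transpose(0, 3, 1, 2)
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        grads.append((x, np.ascontiguousarray(gxp)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def zero_insert(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride - 1`` zeros between rows/cols (transposed-conv helper)."""
    if stride == 1:
        return x
    N, C, H, W = x.data.shape
    out_data = np.zeros((N, C, (H - 1) * stride + 1, (W - 1) * stride + 1),
                        dtype=x.data.dtype)
    out_data[:, :, ::stride, ::stride] = x.data
    return _node(out_data, (x,),
                 lambda g: ((x, g[:, :, ::stride, ::stride]),))


def flip_kernel(w: Tensor) -> Tensor:
    """Spatially flip and transpose in/out channels of an IOHW weight."""
    out_data = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    return _node(out_data, (w,),
                 lambda g: ((w, np.ascontiguousarray(
                     g.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])),))


# ---------------------------------------------------------------------
# bilinear upsampling
# ---------------------------------------------------------------------

_BILINEAR_CACHE: dict = {}


def _bilinear_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Row-stochastic (n_out, n_in) interpolation matrix, half-pixel centres."""
    key = (n_in, n_out, np.dtype(dtype).str)
    mat = _BILINEAR_CACHE.get(key)
    if mat is None:
        mat = np.zeros((n_out, n_in))
        scale = n_in / n_out
        src = (np.arange(n_out) + 0.5) * scale - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = src - lo
        mat[np.arange(n_out), lo] += 1.0 - frac
        mat[np.arange(n_out), hi] += frac
        mat = mat.astype(dtype)
        _BILINEAR_CACHE[key] = mat
    return mat


def bilinear_upsample(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Differentiable separable bilinear resize to ``out_hw``.

    Rows of the interpolation matrices sum to one, so constants are
    preserved exactly.
    """
    N, C, H, W = x.data.shape
    OHt, OWt = out_hw
    if (OHt, OWt) == (H, W):
        return x
    R = _bilinear_matrix(H, OHt, x.data.dtype)
    Cm = _bilinear_matrix(W, OWt, x.data.dtype)
    out_data = np.einsum("oh,nchw,pw->ncop", R, x.data, Cm, optimize=True)

    def backward(g):
        gx = np.einsum("oh,ncop,pw->nchw", R, g, Cm, optimize=True)
        return ((x, gx),)

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------------
# batch normalisation (fused, NCHW)
# ---------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, *,
               mean: np.ndarray | None = None, var: np.ndarray | None = None,
               eps: float = 1e-5):
    """Channel-wise normalisation y = gamma*(x-mu)/sqrt(var+eps) + beta.

    With ``mean``/``var`` omitted they are computed from the batch (training
    mode) and the standard batch-norm backward is used; when provided
    (running statistics, evaluation) they are treated as constants.
    Returns ``(out, batch_mean, batch_var)``.
    """
    axes = (0, 2, 3)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    from_batch = mean is None
    if from_batch:
        mean = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        ggamma = (g * xhat).sum(axis=axes, keepdims=True)
        gbeta = g.sum(axis=axes, keepdims=True)
        gxhat = g * gamma.data
        if from_batch:
            gx = (inv_std / m) * (m * gxhat
                                  - gxhat.sum(axis=axes, keepdims=True)
                                  - xhat * (gxhat * xhat).sum(axis=axes,
                                                              keepdims=True))
        else:
            gx = gxhat * inv_std
        return ((x, gx.astype(x.data.dtype, copy=False)),
                (gamma, ggamma), (beta, gbeta))

    node = _node(out_data, (x, gamma, beta), backward)
    return node, mean, var


# ---------------------------------------------------------------------
# dropout
# ---------------------------------------------------------------------

def dropout(x: Tensor, keep_prob: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    """Inverted dropout: keep with probability ``keep_prob`` and rescale by
    1/keep_prob so the expectation is unchanged; identity in evaluation."""
    if not 0.0 < keep_prob <= 1.0:
        raise ValueError(f"keep_prob must lie in (0, 1], got {keep_prob}")
    if not training or keep_prob == 1.0:
        return x
    mask = (rng.random(x.data.shape) < keep_prob).astype(x.data.dtype) / keep_prob
    return _node(x.data * mask, (x,), lambda g: ((x, g * mask),))
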