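"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the spectrum encoder: dense layers, dilated 1-D
convolution (im2col), pooling, elementwise nonlinearities, row-wise L2
normalization, and fused loss heads (margin cross-entropy on cosine logits,
mean squared error).  Tape-based: every op records its parents and a
backward closure; ``backward()`` topologically sorts the tape and
accumulates gradients.  float32 throughout; fully deterministic.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _make(data, parents, backward) -> Tensor:
    if any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=tuple(parents), backward=backward)
    return Tensor(data)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s)

    return _make(a.data * s, (a,), backward)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """a (..., n) @ b (n, m)."""
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            ga = a.data.reshape(-1, a.data.shape[-1]).T @ g.reshape(-1, g.shape[-1])
            b._accumulate(ga)

    return _make(out_data, (a, b), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return add(matmul(x, w), b)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return _make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = x.data.shape

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(orig))

    return _make(x.data.reshape(shape), (x,), backward)


def take_channel(x: Tensor, c: int) -> Tensor:
    """Select channel c of a (B, C, L) tensor -> (B, L)."""

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[:, c, :] = g
            x._accumulate(dx)

    return _make(x.data[:, c, :], (x,), backward)


def transpose2d(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accumulate(g.T)

    return _make(x.data.T, (x,), backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Same-length dilated 1-D convolution.

    x: (B, Cin, L); w: (Cout, Cin, K) with K odd; b: (Cout,).
    """
    B, Cin, L = x.data.shape
    Cout, _, K = w.data.shape
    pad = dilation * (K - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    idx = np.arange(L)[None, :] + dilation * np.arange(K)[:, None]  # (K, L)
    cols = xp[:, :, idx]  # (B, Cin, K, L)
    cols2 = cols.reshape(B, Cin * K, L)
    w2 = w.data.reshape(Cout, Cin * K)
    out_data = np.matmul(w2, cols2) + b.data[None, :, None]

    def backward(g):
        # g: (B, Cout, L)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.einsum("bol,bcl->oc", g, cols2, optimize=True)
            w._accumulate(gw.reshape(Cout, Cin, K))
        if x.requires_grad:
            dcols2 = np.matmul(w2.T, g)  # (B, Cin*K, L)
            dcols = dcols2.reshape(B, Cin, K, L)
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, :, k * dilation : k * dilation + L] += dcols[:, :, k, :]
            x._accumulate(dxp[:, :, pad : pad + L] if pad else dxp)

    return _make(out_data, (x, w, b), backward)


def avg_pool2(x: Tensor) -> Tensor:
    """Average pooling, kernel 2 stride 2, over the last axis (even length)."""
    B, C, L = x.data.shape
    if L % 2:
        raise ValueError("avg_pool2 requires even length")
    out_data = 0.5 * (x.data[:, :, 0::2] + x.data[:, :, 1::2])

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[:, :, 0::2] = 0.5 * g
            dx[:, :, 1::2] = 0.5 * g
            x._accumulate(dx)

    return _make(out_data, (x,), backward)


def l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Row-wise L2 normalization of (B, d)."""
    norms = np.sqrt((x.data**2).sum(axis=1, keepdims=True)) + eps
    out_data = x.data / norms

    def backward(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=1, keepdims=True)
            x._accumulate((g - out_data * dot) / norms)

    return _make(out_data, (x,), backward)


def margin_cross_entropy(logits: Tensor, labels: np.ndarray, s: float, m: float) -> Tensor:
    """Additive-margin softmax cross-entropy on cosine logits.

    Per-sample loss: -log softmax(s * (logits - m * onehot))[label],
    averaged over the batch.  With m=0, s=1 this reduces exactly to softmax
    cross-entropy on the raw logits.
    """
    B, K = logits.data.shape
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= K:
        raise IndexError("label out of range")
    adj = logits.data.astype(np.float64)
    adj[np.arange(B), labels] -= m
    z = s * adj
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    nll = -np.log(np.clip(p[np.arange(B), labels], 1e-300, None))
    out_data = np.float32(nll.mean())

    def backward(g):
        if logits.requires_grad:
            d = p.copy()
            d[np.arange(B), labels] -= 1.0
            logits._accumulate(((float(g) * s / B) * d).astype(np.float32))

    return _make(out_data, (logits,), backward)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - target
    out_data = np.float32((diff**2).mean())

    def backward(g):
        if pred.requires_grad:
            pred._accumulate(float(g) * 2.0 * diff / diff.size)

    return _make(out_data, (pred,), backward)
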