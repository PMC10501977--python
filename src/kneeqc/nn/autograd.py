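"""Minimal reverse-mode autodiff over numpy arrays.

Just enough machinery for a convolutional heatmap-regression network:
2-D convolution, ReLU, elementwise add, channel concatenation,
nearest-neighbor upsampling and mean-squared-error loss.  Arrays are NCHW
float32; gradients are accumulated by a topological backward sweep.  All
operations are plain numpy and bit-deterministic on a single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "conv2d", "relu", "add", "scale", "concat", "upsample_nearest", "upsample_bilinear", "mse_loss"]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data: np.ndarray, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents: tuple[Tensor, ...] = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order; graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


def conv2d(x: Tensor, w: Parameter, b: Parameter, stride: int = 1, pad: int = 1) -> Tensor:
    """NCHW convolution with an (O, C, kh, kw) kernel and per-channel bias."""
    xd = x.data
    n, c, h, wd_ = xd.shape
    o, cin, kh, kw = w.data.shape
    assert cin == c, f"channel mismatch: input {c}, kernel {cin}"
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else xd
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd_ + 2 * pad - kw) // stride + 1
    out = np.zeros((n, o, ho, wo), dtype=np.float32)
    for u in range(kh):
        for v in range(kw):
            xs = xp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride]
            out += np.einsum("nchw,oc->nohw", xs, w.data[:, :, u, v], optimize=True)
    out += b.data[None, :, None, None]

    def _bw(gy: np.ndarray) -> None:
        if b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2, 3)))
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for u in range(kh):
            for v in range(kw):
                xs = xp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride]
                if w.requires_grad:
                    gw_uv = np.einsum("nohw,nchw->oc", gy, xs, optimize=True)
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, u, v] += gw_uv
                if gxp is not None:
                    gxp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride] += (
                        np.einsum("nohw,oc->nchw", gy, w.data[:, :, u, v], optimize=True)
                    )
        if gxp is not None:
            gx = gxp[:, :, pad : pad + h, pad : pad + wd_] if pad else gxp
            x._accumulate(gx)

    return Tensor(out, parents=(x, w, b), backward=_bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def _bw(gy: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(gy * mask)

    return Tensor(x.data * mask, parents=(x,), backward=_bw)


def add(a: Tensor, b: Tensor) -> Tensor:
    def _bw(gy: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(gy)
        if b.requires_grad:
            b._accumulate(gy)

    return Tensor(a.data + b.data, parents=(a, b), backward=_bw)


def scale(x: Tensor, c: float) -> Tensor:
    def _bw(gy: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(gy * np.float32(c))

    return Tensor(x.data * np.float32(c), parents=(x,), backward=_bw)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(gy: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(gy[:, lo:hi])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=1),
        parents=tuple(tensors),
        backward=_bw,
    )


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def _bw(gy: np.ndarray) -> None:
        if x.requires_grad:
            n, c, h, w = x.data.shape
            g = gy.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            x._accumulate(g)

    return Tensor(out, parents=(x,), backward=_bw)


def _bilinear_matrix(n_in: int, factor: int) -> np.ndarray:
    """(n_in*factor, n_in) interpolation weights, half-pixel-center convention."""
    n_out = n_in * factor
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    lo = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    hi = np.clip(lo + 1, 0, n_in - 1)
    frac = np.clip(src - lo, 0.0, 1.0)
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    mat[np.arange(n_out), lo] += 1.0 - frac
    mat[np.arange(n_out), hi] += frac
    return mat


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.data.shape
    ar = _bilinear_matrix(h, factor)
    ac = _bilinear_matrix(w, factor)
    out = np.einsum("ij,ncjk,lk->ncil", ar, x.data, ac, optimize=True)

    def _bw(gy: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(np.einsum("ij,ncil,lk->ncjk", ar, gy, ac, optimize=True))

    return Tensor(out, parents=(x,), backward=_bw)


def batch_norm(
    x: Tensor,
    gamma: Parameter,
    beta: Parameter,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode the batch statistics are used and the running buffers
    are updated in place; in inference mode the running buffers are used, so
    prediction is deterministic and batch-size independent.
    """
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def _bw(gy: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accumulate((gy * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            g = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                m = gy.shape[0] * gy.shape[2] * gy.shape[3]
                mean_gy = gy.mean(axis=(0, 2, 3), keepdims=True)
                mean_gy_xhat = (gy * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accumulate(g * (gy - mean_gy - xhat * mean_gy_xhat))
            else:
                x._accumulate(g * gy)

    return Tensor(out.astype(np.float32), parents=(x, gamma, beta), backward=_bw)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error over every element."""
    diff = pred.data - np.asarray(target, dtype=np.float32)

    def _bw(gy: np.ndarray) -> None:
        if pred.requires_grad:
            pred._accumulate(gy * 2.0 * diff / diff.size)

    return Tensor(np.array(np.mean(diff**2), dtype=np.float32), parents=(pred,), backward=_bw)
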