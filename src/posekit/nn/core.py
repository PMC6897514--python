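"""Minimal reverse-mode autodiff over numpy arrays.

A :class:`Tensor` wraps an ``(B, H, W, C)`` (or any-shape) numpy array and
records the operation that produced it; :meth:`Tensor.backward` walks the
tape in reverse topological order accumulating gradients.  Only the
operations needed by fully-convolutional pose models are provided: 2-D
convolution (stride 1 or 2, "same" padding), batch normalisation, ReLU,
2x2 pooling, nearest-neighbour upsampling, channel concatenation,
elementwise add/scale, and mean-squared-error loss.

Convolutions are evaluated as a sum of kernel-offset matrix products
(one GEMM per tap), which keeps memory flat and is fast for the small
channel counts used here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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

        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """Trainable tensor (always requires grad)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------------
# ops


def conv2d(x: Tensor, w: Parameter, b: Parameter, stride: int = 1) -> Tensor:
    """'Same'-padded 2-D convolution in NHWC layout.

    ``w`` has shape ``(kh, kw, Cin, Cout)``; stride 1 preserves the spatial
    size, stride 2 halves it (input sizes must be even).
    """
    kh, kw, cin, cout = w.shape
    bsz, h, ww_, cin2 = x.shape
    assert cin == cin2, "channel mismatch"
    ph, pw = kh // 2, kw // 2
    ho, wo = h // stride, ww_ // stride
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))

    out = np.zeros((bsz * ho * wo, cout), dtype=x.data.dtype)
    slabs = []
    for di in range(kh):
        for dj in range(kw):
            xs = xp[:, di : di + stride * ho : stride,
                    dj : dj + stride * wo : stride, :]
            flat = xs.reshape(-1, cin)
            slabs.append(flat)
            out += flat @ w.data[di, dj]
    out += b.data
    y = out.reshape(bsz, ho, wo, cout)

    def backward(grad: np.ndarray) -> None:
        g = grad.reshape(-1, cout)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for idx, (di, dj) in enumerate(
                (i, j) for i in range(kh) for j in range(kw)
            ):
                gw[di, dj] = slabs[idx].T @ g
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    gflat = g @ w.data[di, dj].T
                    gxp[:, di : di + stride * ho : stride,
                        dj : dj + stride * wo : stride, :] += gflat.reshape(
                        bsz, ho, wo, cin
                    )
            x._accumulate(gxp[:, ph : ph + h, pw : pw + ww_, :])

    return Tensor(y, parents=(x, w, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    y = x.data * mask

    def backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(grad * mask)

    return Tensor(y, parents=(x,), backward=backward)


def batch_norm(
    x: Tensor,
    gamma: Parameter,
    beta: Parameter,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    train: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over the (B, H, W) axes.

    In training mode batch statistics are used and the running statistics
    are updated in place; in eval mode the running statistics are used.
    """
    axes = (0, 1, 2)
    n = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
    if train:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    y = gamma.data * xhat + beta.data

    def backward(grad: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accumulate((grad * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(grad.sum(axis=axes))
        if x.requires_grad:
            if train:
                gxhat = grad * gamma.data
                gx = (
                    gxhat
                    - gxhat.mean(axis=axes)
                    - xhat * (gxhat * xhat).sum(axis=axes) / n
                ) * inv_std
            else:
                gx = grad * gamma.data * inv_std
            x._accumulate(gx)

    return Tensor(y, parents=(x, gamma, beta), backward=backward)


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2 (spatial sizes must be even)."""
    bsz, h, w, c = x.shape
    r = x.data.reshape(bsz, h // 2, 2, w // 2, 2, c)
    win = r.transpose(0, 1, 3, 5, 2, 4).reshape(bsz, h // 2, w // 2, c, 4)
    arg = win.argmax(axis=-1)
    y = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            gwin = np.zeros_like(win)
            np.put_along_axis(gwin, arg[..., None], grad[..., None], axis=-1)
            gx = gwin.reshape(bsz, h // 2, w // 2, c, 2, 2).transpose(
                0, 1, 4, 2, 5, 3
            ).reshape(bsz, h, w, c)
            x._accumulate(gx)

    return Tensor(y, parents=(x,), backward=backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2."""
    bsz, h, w, c = x.shape
    r = x.data.reshape(bsz, h // 2, 2, w // 2, 2, c)
    y = r.mean(axis=(2, 4))

    def backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            gx = np.repeat(np.repeat(grad, 2, axis=1), 2, axis=2) * 0.25
            x._accumulate(gx)

    return Tensor(y, parents=(x,), backward=backward)


def upsample2(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling."""
    y = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            bsz, h2, w2, c = grad.shape
            gx = grad.reshape(bsz, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))
            x._accumulate(gx)

    return Tensor(y, parents=(x,), backward=backward)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel (last) axis."""
    y = np.concatenate([t.data for t in tensors], axis=-1)
    sizes = [t.shape[-1] for t in tensors]
    bounds = np.cumsum([0] + sizes)

    def backward(grad: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, bounds[:-1], bounds[1:]):
            if t.requires_grad:
                t._accumulate(grad[..., lo:hi])

    return Tensor(y, parents=tuple(tensors), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data

    def backward(grad: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(grad)
        if b.requires_grad:
            b._accumulate(grad)

    return Tensor(y, parents=(a, b), backward=backward)


def scale(x: Tensor, factor: float) -> Tensor:
    y = x.data * factor

    def backward(grad: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(grad * factor)

    return Tensor(y, parents=(x,), backward=backward)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    diff = pred.data - target
    y = np.array((diff**2).mean(), dtype=pred.data.dtype)

    def backward(grad: np.ndarray) -> None:
        if pred.requires_grad:
            pred._accumulate(grad * 2.0 * diff / diff.size)

    return Tensor(y, parents=(pred,), backward=backward)
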