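"""Autograd tensor and the differentiable array operations.

The graph is built eagerly: every op returns a :class:`Tensor` holding a
closure that propagates the upstream gradient to its parents.  Calling
``backward()`` on a scalar loss runs the closures in reverse topological
order.  Operations preserve the floating dtype of their inputs:
float64 for exact gradient checking, float32 for fast CPU training
(both fully deterministic given a seed).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor (weights and biases)."""

    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad for t in tensors)


def _result(data, parents, backward) -> Tensor:
    if _needs_grad(*parents):
        return Tensor(data, requires_grad=True, parents=tuple(parents), backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return _result(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return _result(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * s * (1.0 - s))

    return _result(s, (x,), backward)


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    out_data = x.data.reshape(n, -1)
    in_shape = x.data.shape

    def backward(g: np.ndarray) -> None:
        x._accumulate(g.reshape(in_shape))

    return _result(out_data, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return _result(out_data, tuple(tensors), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    keep = 1.0 - p
    mask = (rng.random(x.data.shape) < keep) / keep
    out_data = x.data * mask

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return _result(out_data, (x,), backward)


# ---------------------------------------------------------------------
# linear algebra layers
# ---------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x (N, I) @ w (I, O) + b (O,)."""
    out_data = x.data @ w.data + b.data

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g @ w.data.T)
        if w.requires_grad:
            w._accumulate(x.data.T @ g)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))

    return _result(out_data, (x, w, b), backward)


def _pad_hw(x: np.ndarray, ph: int, pw: int, value: float = 0.0) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(
        x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=value
    )


def _out_len(L: int, k: int, s: int, p: int) -> int:
    return (L + 2 * p - k) // s + 1


def conv2d(
    x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0
) -> Tensor:
    """2-D convolution (cross-correlation): x (N,C,H,W), w (F,C,KH,KW)."""
    N, C, H, W = x.data.shape
    F, _, KH, KW = w.data.shape
    s, p = stride, padding
    OH, OW = _out_len(H, KH, s, p), _out_len(W, KW, s, p)
    if OH < 1 or OW < 1:
        raise ValueError(
            f"conv output would be empty for input {H}x{W}, kernel {KH}x{KW}"
        )
    xp = _pad_hw(x.data, p, p)
    # im2col: gather the KH*KW shifted views, then one big matmul
    cols = np.empty((N, C, KH, KW, OH, OW), dtype=xp.dtype)
    for i in range(KH):
        for j in range(KW):
            cols[:, :, i, j] = xp[:, :, i : i + s * OH : s, j : j + s * OW : s]
    colmat = cols.transpose(0, 4, 5, 1, 2, 3).reshape(N * OH * OW, C * KH * KW)
    wmat = w.data.reshape(F, -1)
    out = colmat @ wmat.T + b.data
    out_data = out.reshape(N, OH, OW, F).transpose(0, 3, 1, 2)

    def backward(g: np.ndarray) -> None:
        gmat = g.transpose(0, 2, 3, 1).reshape(N * OH * OW, F)
        if b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if w.requires_grad:
            w._accumulate((gmat.T @ colmat).reshape(w.data.shape))
        if x.requires_grad:
            gcol = (gmat @ wmat).reshape(N, OH, OW, C, KH, KW)
            gcol = gcol.transpose(0, 3, 4, 5, 1, 2)  # (N,C,KH,KW,OH,OW)
            gxp = np.zeros_like(xp)
            for i in range(KH):
                for j in range(KW):
                    gxp[:, :, i : i + s * OH : s, j : j + s * OW : s] += gcol[
                        :, :, i, j
                    ]
            gx = gxp[:, :, p : p + H, p : p + W] if p else gxp
            x._accumulate(gx)

    return _result(out_data, (x, w, b), backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor, stride: int) -> Tensor:
    """Transposed convolution ("up-convolution"): x (N,C,H,W), w (C,F,KH,KW).

    Output spatial size is (H-1)*stride + KH.  Used by the U-Net decoder
    with kernel 2, stride 2 to double the resolution.
    """
    N, C, H, W = x.data.shape
    _, F, KH, KW = w.data.shape
    s = stride
    OH, OW = (H - 1) * s + KH, (W - 1) * s + KW
    xt = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N,H,W,F,KH,KW)
    out_data = np.zeros((N, F, OH, OW), dtype=x.data.dtype)
    for i in range(KH):
        for j in range(KW):
            out_data[:, :, i : i + s * H : s, j : j + s * W : s] += xt[
                ..., i, j
            ].transpose(0, 3, 1, 2)
    out_data += b.data[None, :, None, None]

    def backward(g: np.ndarray) -> None:
        gwin = np.empty((N, F, KH, KW, H, W), dtype=g.dtype)
        for i in range(KH):
            for j in range(KW):
                gwin[:, :, i, j] = g[:, :, i : i + s * H : s, j : j + s * W : s]
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(np.einsum("nfijhw,nchw->cfij", gwin, x.data))
        if x.requires_grad:
            x._accumulate(np.einsum("nfijhw,cfij->nchw", gwin, w.data))

    return _result(out_data, (x, w, b), backward)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    N, C, H, W = x.data.shape
    k, s, p = kernel, stride, padding
    OH, OW = _out_len(H, k, s, p), _out_len(W, k, s, p)
    xp = _pad_hw(x.data, p, p, value=-np.inf)
    stack = np.empty((N, C, k * k, OH, OW), dtype=xp.dtype)
    m = 0
    for i in range(k):
        for j in range(k):
            stack[:, :, m] = xp[:, :, i : i + s * OH : s, j : j + s * OW : s]
            m += 1
    idx = stack.argmax(axis=2)
    out_data = np.take_along_axis(stack, idx[:, :, None], axis=2)[:, :, 0]

    def backward(g: np.ndarray) -> None:
        gxp = np.zeros_like(xp)
        m = 0
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + s * OH : s, j : j + s * OW : s] += g * (idx == m)
                m += 1
        gx = gxp[:, :, p : p + H, p : p + W] if p else gxp
        x._accumulate(gx)

    return _result(out_data, (x,), backward)


def adaptive_avg_pool2d(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Average pooling to a fixed output size with torch-style bins."""
    N, C, H, W = x.data.shape
    hb = [(o * H // out_h, -(-(o + 1) * H // out_h)) for o in range(out_h)]
    wb = [(o * W // out_w, -(-(o + 1) * W // out_w)) for o in range(out_w)]
    out_data = np.empty((N, C, out_h, out_w), dtype=x.data.dtype)
    for oi, (h0, h1) in enumerate(hb):
        for oj, (w0, w1) in enumerate(wb):
            out_data[:, :, oi, oj] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def backward(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        for oi, (h0, h1) in enumerate(hb):
            for oj, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                gx[:, :, h0:h1, w0:w1] += g[:, :, oi : oi + 1, oj : oj + 1] / area
        x._accumulate(gx)

    return _result(out_data, (x,), backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Channelwise batch normalization; updates running stats in place."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = g * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gx = (
                    gs
                    - gs.mean(axis=(0, 2, 3), keepdims=True)
                    - xhat
                    * (gs * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    / m
                ) * inv_std[None, :, None, None]
            else:
                gx = gs * inv_std[None, :, None, None]
            x._accumulate(gx)

    return _result(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------

def log_softmax(z: np.ndarray) -> np.ndarray:
    zmax = z.max(axis=1, keepdims=True)
    logsum = np.log(np.exp(z - zmax).sum(axis=1, keepdims=True)) + zmax
    return z - logsum


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood over integer labels (N,)."""
    n = logits.data.shape[0]
    lsm = log_softmax(logits.data)
    loss = -lsm[np.arange(n), labels].mean()

    def backward(g: np.ndarray) -> None:
        probs = np.exp(lsm)
        probs[np.arange(n), labels] -= 1.0
        logits._accumulate(g * probs / n)

    return _result(np.asarray(loss), (logits,), backward)


def bce_loss(probs: Tensor, targets: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy on probabilities in (0,1)."""
    p = np.clip(probs.data, eps, 1.0 - eps)
    t = np.asarray(targets, dtype=np.float64)
    loss = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean()

    def backward(g: np.ndarray) -> None:
        n = p.size
        probs._accumulate(g * (p - t) / (p * (1.0 - p)) / n)

    return _result(np.asarray(loss), (probs,), backward)


def softmax(z: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(z))
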