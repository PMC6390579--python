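"""Minimal tape-based reverse-mode automatic differentiation over NumPy arrays.

Only the fused operations the binding-residue network needs are provided:
1-D convolution along the sequence axis (via im2col), dense 1x1 projections,
layer normalization over channels, the gated linear unit, dropout, masking,
residual addition, and a masked softmax cross-entropy head.  Everything is
float64; gradients are exact up to floating point and are verified against
central finite differences in the test suite.

Tensors form a DAG through their parents; ``backward`` runs a topological
sort from the loss and calls each node's backward closure, accumulating
gradients into ``Tensor.grad``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "conv1d",
    "dropout",
    "glu",
    "layer_norm",
    "linear",
    "l2_penalty",
    "mask_rows",
    "masked_cross_entropy",
    "scale",
    "shift_sequence",
    "backward",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "parents", "bwd", "requires_grad", "name")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        bwd: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = requires_grad
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(name={self.name!r}, shape={self.data.shape})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def backward(loss: Tensor) -> None:
    """Run reverse-mode accumulation from a scalar loss tensor."""
    if loss.data.size != 1:
        raise ValueError("backward requires a scalar loss")
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:  # iterative DFS post-order; deep graphs exceed recursion limits
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    loss.accumulate(np.ones_like(loss.data))
    for node in reversed(order):
        if node.bwd is not None and node.grad is not None:
            node.bwd(node.grad)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise addition of two same-shape tensors (residual connection)."""
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"add: shape mismatch {a.data.shape} vs {b.data.shape}")
    out = Tensor(a.data + b.data, (a, b))

    def bwd(g: np.ndarray) -> None:
        a.accumulate(g)
        b.accumulate(g)

    out.bwd = bwd
    return out


def scale(a: Tensor, factor: float) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(a.data * factor, (a,))

    def bwd(g: np.ndarray) -> None:
        a.accumulate(g * factor)

    out.bwd = bwd
    return out


def mask_rows(x: Tensor, mask: np.ndarray) -> Tensor:
    """Zero rows where ``mask`` is False.  x: (..., m, C); mask: (..., m) bool."""
    x = _as_tensor(x)
    m = np.asarray(mask, dtype=bool)[..., None]
    out = Tensor(np.where(m, x.data, 0.0), (x,))

    def bwd(g: np.ndarray) -> None:
        x.accumulate(np.where(m, g, 0.0))

    out.bwd = bwd
    return out


def shift_sequence(x: Tensor, offset: int) -> Tensor:
    """Shift along the sequence axis (axis -2), filling vacated rows with zero.

    ``offset=+1`` delays the sequence (out[i] = x[i-1], out[0] = 0), exposing
    only the left context; ``offset=-1`` advances it (out[i] = x[i+1]).
    """
    x = _as_tensor(x)
    out_data = np.zeros_like(x.data)
    if offset > 0:
        out_data[..., offset:, :] = x.data[..., :-offset, :]
    elif offset < 0:
        out_data[..., :offset, :] = x.data[..., -offset:, :]
    else:
        out_data[...] = x.data
    out = Tensor(out_data, (x,))

    def bwd(g: np.ndarray) -> None:
        gx = np.zeros_like(x.data)
        if offset > 0:
            gx[..., :-offset, :] = g[..., offset:, :]
        elif offset < 0:
            gx[..., -offset:, :] = g[..., :offset, :]
        else:
            gx[...] = g
        x.accumulate(gx)

    out.bwd = bwd
    return out


def glu(x: Tensor) -> Tensor:
    """Gated linear unit g([A B]) = A * sigmoid(B), halving the channel axis."""
    x = _as_tensor(x)
    ch = x.data.shape[-1]
    if ch % 2 != 0:
        raise ValueError(f"glu requires an even channel count, got {ch}")
    half = ch // 2
    a = x.data[..., :half]
    b = x.data[..., half:]
    sig = 1.0 / (1.0 + np.exp(-b))
    out = Tensor(a * sig, (x,))

    def bwd(g: np.ndarray) -> None:
        gx = np.empty_like(x.data)
        gx[..., :half] = g * sig
        gx[..., half:] = g * a * sig * (1.0 - sig)
        x.accumulate(gx)

    out.bwd = bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    x = _as_tensor(x)
    if not training or rate == 0.0:
        return x
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    out = Tensor(x.data * keep, (x,))

    def bwd(g: np.ndarray) -> None:
        x.accumulate(g * keep)

    out.bwd = bwd
    return out


# ---------------------------------------------------------------------------
# parametric layers
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Dense projection over the channel axis: (..., Cin) @ (Cin, Cout) [+ b].

    This is the 1x1 convolution of the decoder's fully connected layers.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents)

    def bwd(g: np.ndarray) -> None:
        x.accumulate(g @ w.data.T)
        lead = x.data.reshape(-1, x.data.shape[-1])
        w.accumulate(lead.T @ g.reshape(-1, g.shape[-1]))
        if b is not None:
            b.accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))

    out.bwd = bwd
    return out


def conv1d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    pad_left: int | None = None,
    pad_right: int | None = None,
) -> Tensor:
    """1-D convolution along the sequence axis.

    x: (B, m, Cin); w: (k, Cin, Cout).  Padding defaults to the symmetric
    (k-1)/2 per side that keeps the output length at m for odd k; causal
    context branches pass explicit one-sided padding with
    pad_left + pad_right = k - 1, which also preserves m.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    k, cin, cout = w.data.shape
    if x.data.shape[-1] != cin:
        raise ValueError(
            f"conv1d: input has {x.data.shape[-1]} channels, kernel expects {cin}"
        )
    if pad_left is None and pad_right is None:
        if k % 2 == 0:
            raise ValueError("conv1d with symmetric padding requires odd k")
        pad_left = pad_right = (k - 1) // 2
    pl = int(pad_left or 0)
    pr = int(pad_right or 0)
    if pl + pr != k - 1:
        raise ValueError("conv1d padding must satisfy pad_left + pad_right == k - 1")

    bsz, m, _ = x.data.shape
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    # im2col: windows (B, m, k, Cin) as a strided view, flattened for matmul
    sw = np.lib.stride_tricks.sliding_window_view(xp, (k,), axis=1)  # (B, m, Cin, k)
    cols = sw.transpose(0, 1, 3, 2).reshape(bsz, m, k * cin)
    wmat = w.data.reshape(k * cin, cout)
    out_data = cols @ wmat
    if b is not None:
        out_data = out_data + b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents)

    def bwd(g: np.ndarray) -> None:
        gcols = g @ wmat.T  # (B, m, k*Cin)
        gcols = gcols.reshape(bsz, m, k, cin)
        gxp = np.zeros_like(xp)
        for j in range(k):  # col2im scatter-add; k is small
            gxp[:, j : j + m, :] += gcols[:, :, j, :]
        x.accumulate(gxp[:, pl : pl + m, :])
        gw = cols.reshape(-1, k * cin).T @ g.reshape(-1, cout)
        w.accumulate(gw.reshape(k, cin, cout))
        if b is not None:
            b.accumulate(g.reshape(-1, cout).sum(axis=0))

    out.bwd = bwd
    return out


def layer_norm(x: Tensor, gain: Tensor, offset: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the channel (last) axis, per residue."""
    x, gain, offset = _as_tensor(x), _as_tensor(gain), _as_tensor(offset)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + offset.data, (x, gain, offset))
    n = x.data.shape[-1]

    def bwd(g: np.ndarray) -> None:
        gg = g * gain.data
        # standard LN backward: dL/dx = inv * (gg - mean(gg) - xhat * mean(gg*xhat))
        m1 = gg.mean(axis=-1, keepdims=True)
        m2 = (gg * xhat).mean(axis=-1, keepdims=True)
        x.accumulate(inv * (gg - m1 - xhat * m2))
        flat = (g * xhat).reshape(-1, n)
        gain.accumulate(flat.sum(axis=0))
        offset.accumulate(g.reshape(-1, n).sum(axis=0))

    out.bwd = bwd
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def masked_cross_entropy(
    logits: Tensor,
    labels: np.ndarray,
    mask: np.ndarray,
    reduction: str = "mean",
) -> Tensor:
    """Softmax cross-entropy over mask-valid residues.

    logits: (B, m, 2); labels: (B, m) in {0, 1}; mask: (B, m) bool.
    ``reduction`` is "mean" (per valid residue) or "sum".  Masked residues
    contribute nothing to the value or the gradient.
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    valid = np.asarray(mask, dtype=bool)
    t = int(valid.sum())
    if t == 0:
        raise ValueError("masked_cross_entropy: no valid residues in batch")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp  # (B, m, 2)
    lab = labels.astype(int)
    nll = -np.take_along_axis(logp, lab[..., None], axis=-1)[..., 0]
    total = float(nll[valid].sum())
    denom = t if reduction == "mean" else 1
    out = Tensor(np.float64(total / denom), (logits,))

    def bwd(g: np.ndarray) -> None:
        probs = np.exp(logp)
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, lab[..., None], 1.0, axis=-1)
        grad = (probs - onehot) * valid[..., None] / denom
        logits.accumulate(grad * g)

    out.bwd = bwd
    return out


def l2_penalty(params: Iterable[Tensor]) -> Tensor:
    """Sum of squared entries over the given parameter tensors."""
    params = list(params)
    value = np.float64(sum(float(np.sum(p.data * p.data)) for p in params))
    out = Tensor(value, tuple(params))

    def bwd(g: np.ndarray) -> None:
        for p in params:
            p.accumulate(2.0 * p.data * g)

    out.bwd = bwd
    return out
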