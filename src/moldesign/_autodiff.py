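"""Minimal reverse-mode automatic differentiation on numpy arrays.

The generator's recurrent networks are trained with this tape-based engine.
Ops are deliberately few: dense algebra, elementwise nonlinearities, embedding
lookup, a fused LSTM layer (backprop-through-time implemented inside a single
node to keep the tape short), softmax and a fused masked cross-entropy.
Gradient correctness is asserted against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "add",
    "sub",
    "mul",
    "scale",
    "matmul",
    "tanh",
    "sigmoid",
    "exp",
    "square",
    "concat",
    "embedding",
    "lstm",
    "gather_time",
    "repeat_time",
    "softmax",
    "masked_cross_entropy",
    "mean_sum",
    "backward",
]


class Tensor:
    """A numpy array plus gradient bookkeeping.

    ``parents`` and ``_backward`` define the reverse pass; leaves created with
    ``requires_grad=True`` accumulate into ``grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.parents = parents
        self._backward = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self):
        self.grad = None


def parameter(array):
    return Tensor(np.asarray(array, dtype=np.float64), requires_grad=True)


def constant(array):
    return Tensor(array, requires_grad=False)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _node(data, parents, backward_fn):
    t = Tensor(data, parents=parents, backward_fn=backward_fn)
    if not t.requires_grad:
        t._backward = None
    return t


def add(a, b):
    def bw(out):
        if a.requires_grad:
            a.accumulate(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(out.grad, b.shape))

    return _node(a.data + b.data, (a, b), bw)


def sub(a, b):
    def bw(out):
        if a.requires_grad:
            a.accumulate(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b.accumulate(-_unbroadcast(out.grad, b.shape))

    return _node(a.data - b.data, (a, b), bw)


def mul(a, b):
    def bw(out):
        if a.requires_grad:
            a.accumulate(_unbroadcast(out.grad * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(out.grad * a.data, b.shape))

    return _node(a.data * b.data, (a, b), bw)


def scale(a, k):
    def bw(out):
        if a.requires_grad:
            a.accumulate(out.grad * k)

    return _node(a.data * k, (a,), bw)


def matmul(a, b):
    """2-D @ 2-D, or (..., D) @ (D, H) with leading axes flattened."""
    ad, bd = a.data, b.data
    lead = ad.shape[:-1]
    a2 = ad.reshape(-1, ad.shape[-1])
    out_data = (a2 @ bd).reshape(*lead, bd.shape[-1])

    def bw(out):
        g2 = out.grad.reshape(-1, bd.shape[-1])
        if a.requires_grad:
            a.accumulate((g2 @ bd.T).reshape(ad.shape))
        if b.requires_grad:
            b.accumulate(a2.T @ g2)

    return _node(out_data, (a, b), bw)


def tanh(a):
    y = np.tanh(a.data)

    def bw(out):
        if a.requires_grad:
            a.accumulate(out.grad * (1.0 - y * y))

    return _node(y, (a,), bw)


def sigmoid(a):
    y = 1.0 / (1.0 + np.exp(-a.data))

    def bw(out):
        if a.requires_grad:
            a.accumulate(out.grad * y * (1.0 - y))

    return _node(y, (a,), bw)


def exp(a):
    y = np.exp(a.data)

    def bw(out):
        if a.requires_grad:
            a.accumulate(out.grad * y)

    return _node(y, (a,), bw)


def square(a):
    def bw(out):
        if a.requires_grad:
            a.accumulate(out.grad * 2.0 * a.data)

    return _node(a.data**2, (a,), bw)


def concat(tensors, axis=-1):
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def bw(out):
        splits = np.cumsum(sizes)[:-1]
        grads = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, grads):
            if t.requires_grad:
                t.accumulate(g)

    return _node(out_data, tuple(tensors), bw)


def embedding(table, ids):
    """Row lookup: table (V, D), ids int array (...,) -> (..., D)."""
    ids = np.asarray(ids)
    out_data = table.data[ids]

    def bw(out):
        if table.requires_grad:
            g = np.zeros_like(table.data)
            np.add.at(g, ids.reshape(-1), out.grad.reshape(-1, table.data.shape[1]))
            table.accumulate(g)

    return _node(out_data, (table,), bw)


def lstm(x, wx, wh, b):
    """Fused LSTM layer: x (B, T, D) -> hidden states (B, T, H).

    Gate weights are packed [i, f, g, o] along the last axis of wx (D, 4H),
    wh (H, 4H), b (4H,). Initial hidden/cell states are zero. The full
    backprop-through-time pass lives inside this node.
    """
    B, T, D = x.data.shape
    H = wh.data.shape[0]
    hs = np.empty((B, T, H))
    cache = []
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    xw = x.data.reshape(-1, D) @ wx.data  # (B*T, 4H), hoisted out of the loop
    xw = xw.reshape(B, T, 4 * H)
    for t in range(T):
        gates = xw[:, t] + h @ wh.data + b.data
        i = 1.0 / (1.0 + np.exp(-gates[:, :H]))
        f = 1.0 / (1.0 + np.exp(-gates[:, H : 2 * H]))
        g = np.tanh(gates[:, 2 * H : 3 * H])
        o = 1.0 / (1.0 + np.exp(-gates[:, 3 * H :]))
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache.append((h, c, i, f, g, o, tc))
        h, c = h_new, c_new
        hs[:, t] = h

    def bw(out):
        dwx = np.zeros_like(wx.data)
        dwh = np.zeros_like(wh.data)
        db = np.zeros_like(b.data)
        dx = np.zeros_like(x.data) if x.requires_grad else None
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = out.grad[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dwx += x.data[:, t].T @ dgates
            dwh += h_prev.T @ dgates
            db += dgates.sum(axis=0)
            if dx is not None:
                dx[:, t] = dgates @ wx.data.T
            dh_next = dgates @ wh.data.T
            dc_next = dc * f
        if x.requires_grad:
            x.accumulate(dx)
        if wx.requires_grad:
            wx.accumulate(dwx)
        if wh.requires_grad:
            wh.accumulate(dwh)
        if b.requires_grad:
            b.accumulate(db)

    return _node(hs, (x, wx, wh, b), bw)


def gather_time(x, idx):
    """Pick one timestep per sequence: x (B, T, H), idx (B,) -> (B, H)."""
    idx = np.asarray(idx)
    B = x.data.shape[0]
    rows = np.arange(B)
    out_data = x.data[rows, idx]

    def bw(out):
        if x.requires_grad:
            g = np.zeros_like(x.data)
            g[rows, idx] = out.grad
            x.accumulate(g)

    return _node(out_data, (x,), bw)


def repeat_time(x, T):
    """Tile a per-sequence vector along time: (B, D) -> (B, T, D)."""
    out_data = np.repeat(x.data[:, None, :], T, axis=1)

    def bw(out):
        if x.requires_grad:
            x.accumulate(out.grad.sum(axis=1))

    return _node(out_data, (x,), bw)


def softmax(a, axis=-1):
    m = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(m)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(out):
        if a.requires_grad:
            dot = (out.grad * y).sum(axis=axis, keepdims=True)
            a.accumulate(y * (out.grad - dot))

    return _node(y, (a,), bw)


def masked_cross_entropy(logits, targets, mask):
    """Mean per-token negative log-likelihood over positions where mask==1.

    logits (B, T, V); targets int (B, T); mask (B, T). Returns a scalar node.
    """
    targets = np.asarray(targets)
    mask = np.asarray(mask, dtype=np.float64)
    m = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(m)
    p = e / e.sum(axis=-1, keepdims=True)
    B, T = targets.shape
    rows = np.repeat(np.arange(B), T)
    cols = np.tile(np.arange(T), B)
    picked = p[rows, cols, targets.reshape(-1)].reshape(B, T)
    n = mask.sum()
    loss = -(np.log(np.clip(picked, 1e-300, None)) * mask).sum() / max(n, 1.0)

    def bw(out):
        if logits.requires_grad:
            g = p.copy()
            g[rows, cols, targets.reshape(-1)] -= 1.0
            g *= (mask / max(n, 1.0))[:, :, None]
            logits.accumulate(g * out.grad)

    return _node(loss, (logits,), bw)


def mean_sum(a, k=1.0):
    """k * sum(a) as a scalar node (use k=1/N for means)."""

    def bw(out):
        if a.requires_grad:
            a.accumulate(np.full_like(a.data, out.grad * k))

    return _node(a.data.sum() * k, (a,), bw)


def backward(loss):
    """Run the reverse pass from a scalar loss node."""
    topo = []
    seen = set()
    stack = [(loss, False)]
    while stack:  # iterative post-order DFS
        node, expanded = stack.pop()
        if expanded:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for t in reversed(topo):
        if t._backward is not None and t.grad is not None:
            t._backward(t)
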