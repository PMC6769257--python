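"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the targeting-peptide network needs are provided; the
LSTM layer is a single fused node with a hand-written backward pass
(back-propagation through time), which keeps the per-step Python overhead to
one graph node per direction.  All gradients are exercised by
finite-difference checks in the test suite.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence

import numpy as np

#: float32 is the working precision; tests may switch to float64
#: for finite-difference gradient checks.
DTYPE = np.float32


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor into the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: List[Tensor] = []
        seen = set()

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
                t._backward()


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(DTYPE, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient g down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs_grad(*parents):
        out._parents = tuple(parents)
        out._backward = backward(out)
    return out


# ---------------------------------------------------------------------------
# Elementwise and linear-algebra ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            if a.requires_grad or a._parents:
                _accum(a, _unbroadcast(out.grad, a.shape))
            if b.requires_grad or b._parents:
                _accum(b, _unbroadcast(out.grad, b.shape))
        return run
    return _make(a.data + b.data, (a, b), bw)


def mul(a: Tensor, b) -> Tensor:
    if not isinstance(b, Tensor):
        bval = DTYPE(b)

        def bw_const(out):
            def run():
                _accum(a, out.grad * bval)
            return run
        return _make(a.data * bval, (a,), bw_const)

    def bw(out):
        def run():
            if a.requires_grad or a._parents:
                _accum(a, _unbroadcast(out.grad * b.data, a.shape))
            if b.requires_grad or b._parents:
                _accum(b, _unbroadcast(out.grad * a.data, b.shape))
        return run
    return _make(a.data * b.data, (a, b), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            g = out.grad
            if a.requires_grad or a._parents:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                _accum(a, _unbroadcast(ga, a.shape))
            if b.requires_grad or b._parents:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                _accum(b, _unbroadcast(gb, b.shape))
        return run
    return _make(np.matmul(a.data, b.data), (a, b), bw)


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)

    def bw(out):
        def run():
            _accum(a, out.grad * (1.0 - y * y))
        return run
    return _make(y, (a,), bw)


def relu(a: Tensor) -> Tensor:
    y = np.maximum(a.data, 0.0)

    def bw(out):
        def run():
            _accum(a, out.grad * (a.data > 0))
        return run
    return _make(y, (a,), bw)


def exp(a: Tensor) -> Tensor:
    y = np.exp(a.data)

    def bw(out):
        def run():
            _accum(a, out.grad * y)
        return run
    return _make(y, (a,), bw)


def reshape(a: Tensor, shape) -> Tensor:
    def bw(out):
        def run():
            _accum(a, out.grad.reshape(a.shape))
        return run
    return _make(a.data.reshape(shape), (a,), bw)


def swapaxes(a: Tensor, ax1: int, ax2: int) -> Tensor:
    def bw(out):
        def run():
            _accum(a, np.swapaxes(out.grad, ax1, ax2))
        return run
    return _make(np.swapaxes(a.data, ax1, ax2), (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]

    def bw(out):
        def run():
            start = 0
            for t, s in zip(tensors, sizes):
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(start, start + s)
                if t.requires_grad or t._parents:
                    _accum(t, out.grad[tuple(sl)])
                start += s
        return run
    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def mean(a: Tensor) -> Tensor:
    n = a.data.size

    def bw(out):
        def run():
            _accum(a, np.full(a.shape, out.grad / n, dtype=DTYPE))
        return run
    return _make(a.data.mean(), (a,), bw)


def dropout(a: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only during training."""
    if rate <= 0.0:
        return a
    keep = (rng.random(a.shape) >= rate).astype(DTYPE) / (1.0 - rate)

    def bw(out):
        def run():
            _accum(a, out.grad * keep)
        return run
    return _make(a.data * keep, (a,), bw)


# ---------------------------------------------------------------------------
# Softmax-family ops
# ---------------------------------------------------------------------------

def masked_log_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Log-softmax over the last axis with exact zeros of probability mass on
    masked-out entries (log-prob -inf).

    ``mask`` broadcasts against ``scores``; True marks valid entries.  Every
    row must contain at least one valid entry.
    """
    m = np.broadcast_to(mask, scores.shape)
    if not m.any(axis=-1).all():
        raise ValueError("masked_log_softmax: a row has no valid positions")
    neg = DTYPE(-np.inf)
    s = np.where(m, scores.data, neg)
    smax = s.max(axis=-1, keepdims=True)
    z = np.where(m, np.exp(s - smax), 0.0)
    denom = z.sum(axis=-1, keepdims=True)
    logp = np.where(m, s - smax - np.log(denom), neg)
    p = z / denom

    def bw(out):
        def run():
            g = np.where(m, out.grad, 0.0)
            _accum(scores, (g - p * g.sum(axis=-1, keepdims=True)).astype(DTYPE))
        return run
    return _make(logp, (scores,), bw)


def pick_mean_negative(logp: Tensor, indices: Sequence[tuple]) -> Tensor:
    """``-mean(logp[idx] for idx in indices)`` — the cross-entropy reduction.

    ``indices`` are full integer index tuples into ``logp``.
    """
    if len(indices) == 0:
        raise ValueError("pick_mean_negative: empty index list")
    idx = tuple(np.array(cols) for cols in zip(*indices))
    n = len(indices)
    val = -logp.data[idx].mean()

    def bw(out):
        def run():
            g = np.zeros(logp.shape, dtype=DTYPE)
            np.add.at(g, idx, -out.grad / n)
            _accum(logp, g)
        return run
    return _make(val, (logp,), bw)


# ---------------------------------------------------------------------------
# Fused LSTM layer (unidirectional; BPTT written by hand)
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm(x: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor, h0: Tensor, c0: Tensor) -> Tensor:
    """Run an LSTM over ``x`` (batch, T, features) and return all hidden states.

    Gate layout along the 4H axis is (input, forget, cell, output).  ``h0`` and
    ``c0`` are (batch, H) initial states; gradients flow back into them, which
    is how the organism-group conditioning is trained.
    """
    B, T, F = x.shape
    H = Wh.shape[0]
    xW = x.data.reshape(B * T, F) @ Wx.data  # (B*T, 4H), precomputed
    xW = xW.reshape(B, T, 4 * H)

    i_s = np.empty((B, T, H), dtype=DTYPE)
    f_s = np.empty_like(i_s)
    g_s = np.empty_like(i_s)
    o_s = np.empty_like(i_s)
    c_s = np.empty_like(i_s)
    tc_s = np.empty_like(i_s)
    h_s = np.empty_like(i_s)

    h = h0.data
    c = c0.data
    for t in range(T):
        z = xW[:, t] + h @ Wh.data + b.data
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        i_s[:, t], f_s[:, t], g_s[:, t], o_s[:, t] = i, f, g, o
        c_s[:, t], tc_s[:, t], h_s[:, t] = c, tc, h

    def bw(out):
        def run():
            gH = out.grad  # (B, T, H)
            dWx = np.zeros_like(Wx.data)
            dWh = np.zeros_like(Wh.data)
            db = np.zeros_like(b.data)
            dx = np.zeros((B, T, F), dtype=DTYPE)
            dh_next = np.zeros((B, H), dtype=DTYPE)
            dc_next = np.zeros((B, H), dtype=DTYPE)
            for t in range(T - 1, -1, -1):
                i, f, g, o = i_s[:, t], f_s[:, t], g_s[:, t], o_s[:, t]
                tc = tc_s[:, t]
                c_prev = c_s[:, t - 1] if t > 0 else c0.data
                h_prev = h_s[:, t - 1] if t > 0 else h0.data
                dh = gH[:, t] + dh_next
                do = dh * tc
                dc = dh * o * (1.0 - tc * tc) + dc_next
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dz = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g * g),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                dWh += h_prev.T @ dz
                db += dz.sum(axis=0)
                dx[:, t] = dz @ Wx.data.T
                x_t = x.data[:, t]
                dWx += x_t.T @ dz
                dh_next = dz @ Wh.data.T
                dc_next = dc * f
            if x.requires_grad or x._parents:
                _accum(x, dx)
            if Wx.requires_grad:
                _accum(Wx, dWx)
            if Wh.requires_grad:
                _accum(Wh, dWh)
            if b.requires_grad:
                _accum(b, db)
            if h0.requires_grad or h0._parents:
                _accum(h0, dh_next)
            if c0.requires_grad or c0._parents:
                _accum(c0, dc_next)
        return run
    return _make(h_s, (x, Wx, Wh, b, h0, c0), bw)


def permute_time(x: Tensor, perm: np.ndarray) -> Tensor:
    """Reorder the time axis per batch row; ``perm`` is (B, T) of indices.

    Used to reverse the valid prefix of each padded sequence so the backward
    LSTM direction runs over real residues only.  The permutations used are
    involutions, so the backward pass applies the same gather.
    """
    B = x.shape[0]
    rows = np.arange(B)[:, None]
    y = x.data[rows, perm]

    def bw(out):
        def run():
            g = np.zeros_like(x.data)
            np.add.at(g, (rows, perm), out.grad)
            _accum(x, g)
        return run
    return _make(y, (x,), bw)


def reverse_perm(lengths: np.ndarray, T: int) -> np.ndarray:
    """(B, T) index array reversing the first ``lengths[i]`` steps of row i."""
    B = len(lengths)
    perm = np.tile(np.arange(T), (B, 1))
    for i, n in enumerate(lengths):
        perm[i, :n] = np.arange(n - 1, -1, -1)
    return perm
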