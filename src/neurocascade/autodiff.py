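"""Minimal reverse-mode automatic differentiation over numpy arrays.

The cascade models fitted by this package (static linear-nonlinear subunits,
gated-recurrent-unit subunits, tempered-softmax synapse assignment) are trained
by gradient descent on a mean-squared-error loss.  This module provides the
differentiation engine: a :class:`Tensor` wrapping a numpy array, a small set
of broadcast-aware primitive operations, two fused operations with hand-derived
backward passes (a causal FIR convolution and a full GRU sequence scan), and an
Adam optimizer.

Every primitive is exercised against central finite differences in the test
suite; the fused GRU backward is additionally checked against a scalar-by-scalar
re-implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "Tensor",
    "add", "sub", "mul", "neg", "matmul", "tanh", "sigmoid", "exp", "log",
    "square", "softplus", "tsum", "tmean", "scale", "add_const", "row",
    "causal_conv", "gru_sequence", "softmax_columns", "mse",
    "Adam",
]


class Tensor:
    """Node in the computation graph.

    Parameters with ``requires_grad=True`` accumulate gradients in ``.grad``
    after :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -----------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from a scalar output.

        Processes nodes in an order where every consumer runs before its
        producers (Kahn's algorithm on pending-consumer counts), so shared
        subexpressions receive their full gradient before propagating it.
        """
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        pending: dict[int, int] = {}
        nodes: dict[int, Tensor] = {id(self): self}
        stack = [self]
        while stack:
            node = stack.pop()
            for p in node._parents:
                if id(p) not in nodes:
                    nodes[id(p)] = p
                    pending[id(p)] = 0
                    stack.append(p)
                pending[id(p)] += 1
        self._accumulate(np.ones_like(self.data))
        ready = [self]
        while ready:
            node = ready.pop()
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            for p in node._parents:
                pending[id(p)] -= 1
                if pending[id(p)] == 0:
                    ready.append(p)

    # operator sugar
    def __add__(self, other):
        return add(self, self._lift(other))

    def __sub__(self, other):
        return sub(self, self._lift(other))

    def __mul__(self, other):
        return mul(self, self._lift(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, self._lift(other))


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs(*parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise / linear primitives ----------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))
    return _make(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(-g, b.data.shape))
    return _make(a.data - b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))
    return _make(a.data * b.data, (a, b), bw)


def neg(a: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(-g)
    return _make(-a.data, (a,), bw)


def scale(a: Tensor, c: float) -> Tensor:
    def bw(g):
        a._accumulate(g * c)
    return _make(a.data * c, (a,), bw)


def add_const(a: Tensor, c) -> Tensor:
    def bw(g):
        a._accumulate(g)
    return _make(a.data + c, (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.data.ndim == 1 and b.data.ndim == 1:  # inner product
            a._accumulate(g * b.data)
            b._accumulate(g * a.data)
        elif a.data.ndim == 2 and b.data.ndim == 1:
            a._accumulate(np.outer(g, b.data))
            b._accumulate(a.data.T @ g)
        elif a.data.ndim == 1 and b.data.ndim == 2:
            a._accumulate(g @ b.data.T)
            b._accumulate(np.outer(a.data, g))
        else:
            a._accumulate(g @ b.data.T)
            b._accumulate(a.data.T @ g)
    return _make(a.data @ b.data, (a, b), bw)


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)

    def bw(g):
        a._accumulate(g * (1.0 - y * y))
    return _make(y, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        a._accumulate(g * y * (1.0 - y))
    return _make(y, (a,), bw)


def exp(a: Tensor) -> Tensor:
    y = np.exp(a.data)

    def bw(g):
        a._accumulate(g * y)
    return _make(y, (a,), bw)


def log(a: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(g / a.data)
    return _make(np.log(a.data), (a,), bw)


def square(a: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(2.0 * g * a.data)
    return _make(a.data * a.data, (a,), bw)


def softplus(a: Tensor) -> Tensor:
    # numerically stable log(1 + e^x); used to keep synaptic weights >= 0
    y = np.logaddexp(0.0, a.data)

    def bw(g):
        a._accumulate(g / (1.0 + np.exp(-a.data)))
    return _make(y, (a,), bw)


def tsum(a: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())
    return _make(a.data.sum(), (a,), bw)


def tmean(a: Tensor) -> Tensor:
    n = a.data.size

    def bw(g):
        a._accumulate(np.broadcast_to(g / n, a.data.shape).copy())
    return _make(a.data.mean(), (a,), bw)


def sum_axis0(a: Tensor) -> Tensor:
    """Sum a 2-D tensor over its first axis."""
    def bw(g):
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())
    return _make(a.data.sum(axis=0), (a,), bw)


def row(a: Tensor, i: int) -> Tensor:
    """Extract row i of a 2-D tensor."""
    def bw(g):
        full = np.zeros_like(a.data)
        full[i] = g
        a._accumulate(full)
    return _make(a.data[i], (a,), bw)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a fixed target array."""
    d = pred.data - target
    n = d.size

    def bw(g):
        pred._accumulate((2.0 / n) * g * d)
    return _make(np.mean(d * d), (pred,), bw)


# -- fused operations --------------------------------------------------------

def causal_conv(signal: Tensor, kernel: Tensor) -> Tensor:
    """Causal discrete convolution ``y[t] = sum_tau kernel[tau] * signal[t-tau]``.

    ``signal`` has length T, ``kernel`` length L (kernel[0] acts on the current
    bin); the output is truncated to length T.
    """
    s, k = signal.data, kernel.data
    T, L = s.shape[0], k.shape[0]
    y = fftconvolve(s, k)[:T]

    def bw(g):
        signal._accumulate(fftconvolve(g, k[::-1])[L - 1:L - 1 + T])
        kernel._accumulate(fftconvolve(g, s[::-1])[T - 1:T - 1 + L])
    return _make(y, (signal, kernel), bw)


def gru_sequence(x: Tensor, wr: Tensor, wz: Tensor, wk: Tensor,
                 Whr: Tensor, Whz: Tensor, Whk: Tensor,
                 br: Tensor, bz: Tensor, bk: Tensor) -> Tensor:
    """Scan a gated recurrent unit over a scalar input sequence.

    The subunit input x(t) is a scalar per time step (summed synaptic drive
    plus child-subunit input); the hidden state h(t) has dimension G.  Gates:

        r(t) = sig(wr x(t) + Whr h(t-1) + br)
        z(t) = sig(wz x(t) + Whz h(t-1) + bz)
        k(t) = tanh(wk x(t) + bk + Whk (r(t) * h(t-1)))
        h(t) = (1 - z(t)) * k(t) + z(t) * h(t-1)

    with h(-1) = 0.  Returns the full hidden trajectory, shape (T, G).
    The backward pass is standard backpropagation through time.
    """
    xs = x.data
    T = xs.shape[0]
    G = br.data.shape[0]
    Wr, Wz, Wk = Whr.data, Whz.data, Whk.data
    vr, vz, vk = wr.data, wz.data, wk.data
    cbr, cbz, cbk = br.data, bz.data, bk.data

    H = np.empty((T, G))
    R = np.empty((T, G))
    Z = np.empty((T, G))
    K = np.empty((T, G))
    h = np.zeros(G)
    for t in range(T):
        xt = xs[t]
        r = 1.0 / (1.0 + np.exp(-(vr * xt + Wr @ h + cbr)))
        z = 1.0 / (1.0 + np.exp(-(vz * xt + Wz @ h + cbz)))
        k = np.tanh(vk * xt + cbk + Wk @ (r * h))
        R[t], Z[t], K[t] = r, z, k
        h = (1.0 - z) * k + z * h
        H[t] = h

    def bw(gH):
        dwr = np.zeros(G); dwz = np.zeros(G); dwk = np.zeros(G)
        dWr = np.zeros((G, G)); dWz = np.zeros((G, G)); dWk = np.zeros((G, G))
        dbr = np.zeros(G); dbz = np.zeros(G); dbk = np.zeros(G)
        dx = np.zeros(T)
        carry = np.zeros(G)
        for t in range(T - 1, -1, -1):
            dh = gH[t] + carry
            h_prev = H[t - 1] if t > 0 else np.zeros(G)
            r, z, k = R[t], Z[t], K[t]
            dz = dh * (h_prev - k)
            dk = dh * (1.0 - z)
            dh_prev = dh * z
            dak = dk * (1.0 - k * k)
            rh_grad = Wk.T @ dak
            dr = rh_grad * h_prev
            dh_prev += rh_grad * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            xt = xs[t]
            dwk += dak * xt; dbk += dak; dWk += np.outer(dak, r * h_prev)
            dwz += daz * xt; dbz += daz; dWz += np.outer(daz, h_prev)
            dwr += dar * xt; dbr += dar; dWr += np.outer(dar, h_prev)
            dh_prev += Wz.T @ daz + Wr.T @ dar
            dx[t] = vr @ dar + vz @ daz + vk @ dak
            carry = dh_prev
        x._accumulate(dx)
        wr._accumulate(dwr); wz._accumulate(dwz); wk._accumulate(dwk)
        Whr._accumulate(dWr); Whz._accumulate(dWz); Whk._accumulate(dWk)
        br._accumulate(dbr); bz._accumulate(dbz); bk._accumulate(dbk)

    return _make(H, (x, wr, wz, wk, Whr, Whz, Whk, br, bz, bk), bw)


def softmax_columns(omega: Tensor, beta: float) -> Tensor:
    """Tempered softmax over rows, independently per column.

    ``C[n, l] = exp(beta * omega[n, l]) / sum_n' exp(beta * omega[n', l])`` —
    each synapse (column l) distributes one unit of assignment over subunits.
    Max-subtraction guards overflow; the result is invariant to adding a
    constant to a column.
    """
    a = beta * omega.data
    a = a - a.max(axis=0, keepdims=True)
    e = np.exp(a)
    C = e / e.sum(axis=0, keepdims=True)

    def bw(g):
        omega._accumulate(beta * C * (g - (g * C).sum(axis=0, keepdims=True)))
    return _make(C, (omega,), bw)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.005,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
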