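"""Cascade-model structures and forward evaluation.

A cascade model is a rooted tree of subunits.  Node 0 is a notional linear
root whose output is the predicted voltage; every other node is either a
*static* subunit (linear temporal filtering of its synaptic drive with
raised-cosine kernels, a tanh nonlinearity, optionally multiplexed over
N_ch channels) or a *dynamic* subunit (a gated recurrent unit, able to
produce transient responses to sustained input).  Synapses reach subunits
through an assignment matrix C_syn (one column per synapse, summing to one;
binary when fixed or after discovery) and nonnegative scalar weights w_syn,
separately for the excitatory and inhibitory streams.

The forward pass here is plain numpy and is the reference implementation;
the fitting module rebuilds the same computation as a differentiable graph
and is tested to agree with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .kernels import KernelBank, eval_kernel
from .morphology import SynapsePlacement, BACKGROUND

__all__ = [
    "StaticSubunitParams", "DynamicSubunitParams", "ArchitectureSpec",
    "CascadeModel", "soft_assignment", "hard_assignment", "gru_step",
    "static_forward", "aggregate_synapses", "filter_spikes",
    "two_layer_architecture", "single_subunit_architecture",
    "discovery_architecture",
]


@dataclass
class StaticSubunitParams:
    """Per-channel output weight, bias and kernel coefficients (exc and inh)."""

    w: np.ndarray        # (n_ch,)
    b: np.ndarray        # (n_ch,)
    alpha_e: np.ndarray  # (n_ch, K)
    alpha_i: np.ndarray  # (n_ch, K)

    @property
    def n_ch(self) -> int:
        return len(self.w)

    def arrays(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b,
                "alpha_e": self.alpha_e, "alpha_i": self.alpha_i}


@dataclass
class DynamicSubunitParams:
    """Gated-recurrent-unit gate parameters plus affine readout."""

    wr: np.ndarray; wz: np.ndarray; wk: np.ndarray        # (G,)
    Whr: np.ndarray; Whz: np.ndarray; Whk: np.ndarray     # (G, G)
    br: np.ndarray; bz: np.ndarray; bk: np.ndarray        # (G,)
    w_out: np.ndarray                                      # (G,)
    b_out: float

    @property
    def G(self) -> int:
        return len(self.br)

    def arrays(self) -> dict[str, np.ndarray]:
        return {"wr": self.wr, "wz": self.wz, "wk": self.wk,
                "Whr": self.Whr, "Whz": self.Whz, "Whk": self.Whk,
                "br": self.br, "bz": self.bz, "bk": self.bk,
                "w_out": self.w_out, "b_out": np.atleast_1d(self.b_out)}


@dataclass
class ArchitectureSpec:
    """Subunit tree, subunit kinds, and the synapse-to-subunit assignment.

    ``C`` is the (N+1) x (N+1) binary connectivity over nodes {0..N} with
    node 0 the linear root: C[n, m] = 1 iff node m feeds node n.  It must be
    a tree rooted at node 0.
    """

    C: np.ndarray
    kinds: list[str]            # length N, 'static' | 'dynamic'
    n_ch: int = 2
    G: int = 20
    C_syn_e: np.ndarray | None = None   # (N, S_e)
    C_syn_i: np.ndarray | None = None   # (N, S_i)
    w_syn_e: np.ndarray | None = None   # (S_e,) nonnegative
    w_syn_i: np.ndarray | None = None

    @property
    def n_subunits(self) -> int:
        return len(self.kinds)

    def validate(self) -> None:
        N = self.n_subunits
        C = np.asarray(self.C)
        if C.shape != (N + 1, N + 1):
            raise ValueError("connectivity C must be (N+1) x (N+1)")
        parents = C.sum(axis=0)
        if parents[0] != 0 or np.any(parents[1:] != 1):
            raise ValueError("C must be a tree rooted at node 0 "
                             "(every subunit has exactly one parent)")
        # reachability from the root (also rejects cycles)
        order = self.eval_order()
        if len(order) != N:
            raise ValueError("C contains nodes unreachable from the root")
        for M in (self.C_syn_e, self.C_syn_i):
            if M is not None and M.shape[0] != N:
                raise ValueError("assignment matrix row count != N")
            if M is not None and not np.allclose(M.sum(axis=0), 1.0, atol=1e-6):
                raise ValueError("assignment columns must sum to 1")
        for w in (self.w_syn_e, self.w_syn_i):
            if w is not None and np.any(np.asarray(w) < 0):
                raise ValueError("synaptic weights must be nonnegative")

    def children(self, n: int) -> np.ndarray:
        return np.flatnonzero(self.C[n])

    def eval_order(self) -> list[int]:
        """Subunit indices in leaf-to-root order (children before parents)."""
        order: list[int] = []
        stack = [0]
        seen = set()
        while stack:
            n = stack[-1]
            kids = [int(m) for m in self.children(n) if m not in seen]
            if kids:
                stack.extend(kids)
                seen.update(kids)
            else:
                stack.pop()
                if n != 0:
                    order.append(n)
        return order


# -- assignment --------------------------------------------------------------


def soft_assignment(omega: np.ndarray, beta: float) -> np.ndarray:
    """Tempered softmax over subunits (rows), per synapse (column).

    Invariant to adding a constant to a column; columns sum to 1.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    a = beta * np.asarray(omega, dtype=float)
    a = a - a.max(axis=0, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=0, keepdims=True)


def hard_assignment(omega: np.ndarray) -> np.ndarray:
    """One-hot argmax per column; ties break toward the lower subunit index."""
    omega = np.asarray(omega)
    out = np.zeros_like(omega, dtype=float)
    out[np.argmax(omega, axis=0), np.arange(omega.shape[1])] = 1.0
    return out


# -- subunit operations -------------------------------------------------------


def filter_spikes(drive: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution of an aggregated spike train with a kernel."""
    n = len(drive)
    return fftconvolve(drive, kernel)[:n]


def aggregate_synapses(C_syn: np.ndarray, w_syn: np.ndarray,
                       spikes_binned: np.ndarray) -> np.ndarray:
    """Per-subunit drive s_n(t) = C_syn[n, :] . (w_syn * s(t)), shape (N, T)."""
    if C_syn.shape[1] != spikes_binned.shape[0]:
        raise ValueError("synapse count mismatch between assignment and spikes")
    return (C_syn * w_syn[None, :]) @ spikes_binned


def static_forward(params: StaticSubunitParams, drive_e: np.ndarray,
                   drive_i: np.ndarray, ybar: np.ndarray | float,
                   bank: KernelBank) -> np.ndarray:
    """y(t) = sum_j w_j tanh(ybar(t) + x_e_j(t) + x_i_j(t) + b_j)."""
    T = len(drive_e)
    y = np.zeros(T)
    for j in range(params.n_ch):
        xe = filter_spikes(drive_e, eval_kernel(bank, params.alpha_e[j]))
        xi = filter_spikes(drive_i, eval_kernel(bank, params.alpha_i[j]))
        y = y + params.w[j] * np.tanh(ybar + xe + xi + params.b[j])
    return y


def gru_step(params: DynamicSubunitParams, x_t: float,
             h_prev: np.ndarray) -> np.ndarray:
    """One GRU update h_t = (1 - z) * k + z * h_prev."""
    if h_prev.shape != (params.G,):
        raise ValueError("hidden state shape mismatch")
    r = 1.0 / (1.0 + np.exp(-(params.wr * x_t + params.Whr @ h_prev + params.br)))
    z = 1.0 / (1.0 + np.exp(-(params.wz * x_t + params.Whz @ h_prev + params.bz)))
    k = np.tanh(params.wk * x_t + params.bk + params.Whk @ (r * h_prev))
    return (1.0 - z) * k + z * h_prev


def dynamic_forward(params: DynamicSubunitParams, drive_e: np.ndarray,
                    drive_i: np.ndarray, ybar: np.ndarray | float) -> np.ndarray:
    """GRU subunit output: affine readout of the hidden trajectory."""
    x = ybar + drive_e - drive_i
    x = np.broadcast_to(x, drive_e.shape)
    h = np.zeros(params.G)
    y = np.empty(len(x))
    for t in range(len(x)):
        h = gru_step(params, x[t], h)
        y[t] = params.w_out @ h + params.b_out
    return y


# -- full model ---------------------------------------------------------------


@dataclass
class CascadeModel:
    """Architecture + parameters + kernel bank; callable on binned spikes.

    ``output_offset``/``output_scale`` de-standardize the root output when the
    model was trained against standardized targets (the affine map is part of
    the model, applied after the linear root).
    """

    arch: ArchitectureSpec
    params: list          # per subunit, Static- or DynamicSubunitParams
    bank: KernelBank = field(default_factory=KernelBank)
    output_offset: float = 0.0
    output_scale: float = 1.0

    def forward(self, exc_binned: np.ndarray, inh_binned: np.ndarray) -> np.ndarray:
        """Predicted voltage trace, same grid as the binned spike trains."""
        arch = self.arch
        arch.validate()
        T = exc_binned.shape[1]
        drives_e = aggregate_synapses(arch.C_syn_e, arch.w_syn_e, exc_binned)
        drives_i = aggregate_synapses(arch.C_syn_i, arch.w_syn_i, inh_binned)
        outputs = np.zeros((arch.n_subunits + 1, T))
        for n in arch.eval_order():
            ybar = outputs[arch.children(n)].sum(axis=0) if len(arch.children(n)) \
                else 0.0
            p = self.params[n - 1]
            if arch.kinds[n - 1] == "static":
                outputs[n] = static_forward(p, drives_e[n - 1], drives_i[n - 1],
                                            ybar, self.bank)
            else:
                outputs[n] = dynamic_forward(p, drives_e[n - 1], drives_i[n - 1],
                                             ybar)
        root = outputs[arch.children(0)].sum(axis=0)
        return self.output_offset + self.output_scale * root


# -- architecture builders ----------------------------------------------------


def _flat_tree(n_subunits: int) -> np.ndarray:
    C = np.zeros((n_subunits + 1, n_subunits + 1))
    C[0, 1:] = 1.0
    return C


def two_layer_architecture(placement: SynapsePlacement, kind: str = "dynamic",
                           n_ch: int = 2, G: int = 20) -> ArchitectureSpec:
    """The hand-set ("correct") two-layer assignment.

    One subunit per synaptic cluster (receiving the cluster plus background
    synapses on the same branch), one subunit per main dendritic subtree for
    the remaining background synapses, and one subunit for the perisomatic
    inhibition.  Distributed inhibitory synapses join their subtree's subunit.
    """
    K = placement.n_clusters
    subtree_of_branch = placement.branch_subtree
    subtrees = sorted(set(int(s) for s in subtree_of_branch))
    N = K + len(subtrees) + 1
    sub_index = {s: K + i for i, s in enumerate(subtrees)}
    inh_soma = N - 1

    S_e, S_i = placement.n_exc, placement.n_inh
    Ce = np.zeros((N, S_e))
    cluster_branches = {c: placement.cluster_branch(c) for c in range(K)}
    branch_to_cluster = {b: c for c, b in cluster_branches.items()}
    for l in range(S_e):
        c = placement.exc_cluster[l]
        if c != BACKGROUND:
            Ce[c, l] = 1.0
        elif int(placement.exc_branch[l]) in branch_to_cluster:
            Ce[branch_to_cluster[int(placement.exc_branch[l])], l] = 1.0
        else:
            Ce[sub_index[subtree_of_branch[int(placement.exc_branch[l])]], l] = 1.0
    Ci = np.zeros((N, S_i))
    for l in range(S_i):
        if placement.inh_perisomatic[l]:
            Ci[inh_soma, l] = 1.0
        else:
            Ci[sub_index[subtree_of_branch[int(placement.inh_branch[l])]], l] = 1.0
    return ArchitectureSpec(_flat_tree(N), [kind] * N, n_ch, G, Ce, Ci,
                            np.ones(S_e), np.ones(S_i))


def single_subunit_architecture(placement: SynapsePlacement,
                                kind: str = "dynamic", n_ch: int = 2,
                                G: int = 20) -> ArchitectureSpec:
    """All synapses onto one subunit (the "single subunit" / global model)."""
    Ce = np.ones((1, placement.n_exc))
    Ci = np.ones((1, placement.n_inh))
    return ArchitectureSpec(_flat_tree(1), [kind], n_ch, G, Ce, Ci,
                            np.ones(placement.n_exc), np.ones(placement.n_inh))


def discovery_architecture(placement: SynapsePlacement, n_subunits: int,
                           kind: str = "dynamic", n_ch: int = 2,
                           G: int = 20) -> ArchitectureSpec:
    """Fully connected start for assignment discovery (C_syn filled later)."""
    N = n_subunits
    Ce = np.full((N, placement.n_exc), 1.0 / N)
    Ci = np.full((N, placement.n_inh), 1.0 / N)
    return ArchitectureSpec(_flat_tree(N), [kind] * N, n_ch, G, Ce, Ci,
                            np.ones(placement.n_exc), np.ones(placement.n_inh))
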