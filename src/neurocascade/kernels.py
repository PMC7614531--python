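"""Raised-cosine temporal basis for the static subunits' synaptic kernels.

A filtering kernel is a nonnegative-lag function built from K = 30 raised
cosine bumps in log-rescaled time,

    kappa(tau) = 1/2 * sum_k alpha_k * g(tau_bar_k) * (cos(tau_bar_k) + 1),
    tau_bar_k(tau) = a_k * log(tau/s + c_k) - phi_k,

where g keeps only the first period of each bump (|tau_bar| <= pi), a_k = 30
and c_k = 1 for all k, and phi_k ranges uniformly from 0 to 14.5 pi.  In these
units the last bump's support ends near tau/s ~= 4.07, so an explicit time
scale ``s`` (ms per rescaled-time unit) maps the bank onto physiological
lags; the default is chosen so the longest bump ends at ~300 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KernelBank", "eval_kernel"]


@dataclass
class KernelBank:
    n_bumps: int = 30
    a: float = 30.0
    c: float = 1.0
    phi_max: float = 14.5 * np.pi
    span_ms: float = 300.0          # lag at which the last bump's support ends
    dt_ms: float = 1.0
    phi: np.ndarray = field(init=False)
    scale: np.ndarray = field(init=False)   # ms per rescaled-time unit
    table: np.ndarray = field(init=False)   # (K, n_lags) bump values

    def __post_init__(self):
        if self.n_bumps < 1:
            raise ValueError("need at least one bump")
        self.phi = np.linspace(0.0, self.phi_max, self.n_bumps)
        end_unit = np.exp((self.phi_max + np.pi) / self.a) - self.c
        self.scale = self.span_ms / end_unit
        n_lags = int(np.ceil(self.span_ms / self.dt_ms)) + 1
        tau = np.arange(n_lags) * self.dt_ms
        tbar = self.a * np.log(tau / self.scale + self.c)[None, :] - self.phi[:, None]
        bump = 0.5 * (np.cos(tbar) + 1.0)
        bump[np.abs(tbar) > np.pi] = 0.0
        self.table = bump

    @property
    def n_lags(self) -> int:
        return self.table.shape[1]

    def peak_lag_ms(self, k: int) -> float:
        """Lag at which bump k peaks (tau_bar_k = 0)."""
        return float(self.scale * (np.exp(self.phi[k] / self.a) - self.c))


def eval_kernel(bank: KernelBank, alpha: np.ndarray) -> np.ndarray:
    """Discretized kernel kappa = alpha . bumps; linear in alpha, zero for tau < 0."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape[-1] != bank.n_bumps:
        raise ValueError(f"expected {bank.n_bumps} coefficients, got {alpha.shape[-1]}")
    return alpha @ bank.table
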