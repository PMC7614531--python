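"""Uniformly sampled voltage traces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoltageTrace"]


@dataclass
class VoltageTrace:
    """A membrane-potential signal (deviation from rest, mV) on a uniform grid.

    ``component`` tags what the trace represents: 'v_soma', 'v_noNa', 'v_Na',
    'v_AP', 'v_full' or 'local:<branch_id>'.
    """

    values: np.ndarray
    dt_ms: float = 1.0
    component: str = "v_soma"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voltage trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return len(self.values) * self.dt_ms

    def same_grid(self, other: "VoltageTrace") -> bool:
        return len(self) == len(other) and self.dt_ms == other.dt_ms
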