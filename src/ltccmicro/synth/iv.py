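"""Synthetic single-channel current-voltage (I-V) datasets.

Mean open amplitudes at each test potential lie on the single-channel
ohmic line ``i = g (V − V_rev)`` plus Gaussian measurement noise; the
downstream OLS conductance fit is tested as parameter recovery against
the generating slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["IVDataset", "gen_iv_dataset"]


@dataclass
class IVDataset:
    """Mean open-channel amplitudes (pA) per test potential (mV)."""

    voltages: np.ndarray  # mV, one entry per measurement
    amplitudes: np.ndarray  # pA, inward negative
    true_conductance: float | None = None  # pS
    true_reversal: float | None = None  # mV

    def mean_by_voltage(self) -> tuple[np.ndarray, np.ndarray]:
        vs = np.unique(self.voltages)
        means = np.array([self.amplitudes[self.voltages == v].mean() for v in vs])
        return vs, means


def gen_iv_dataset(
    true_conductance: float,
    reversal: float,
    voltages: Sequence[float],
    noise_sd: float = 0.05,
    n_repeats: int = 1,
    seed: int = 0,
) -> IVDataset:
    """Generate amplitudes on ``i = g (V − V_rev)`` with Gaussian noise.

    ``true_conductance`` in pS, potentials in mV, amplitudes in pA.
    """
    voltages = np.asarray(voltages, dtype=float)
    if np.unique(voltages).size < 2:
        raise ValueError("at least two distinct voltages are required for an I-V line")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    v = np.tile(voltages, n_repeats)
    amp = true_conductance * 1e-3 * (v - reversal)
    if noise_sd > 0:
        amp = amp + rng.normal(0.0, noise_sd, size=v.size)
    return IVDataset(voltages=v, amplitudes=amp,
                     true_conductance=float(true_conductance), true_reversal=float(reversal))
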