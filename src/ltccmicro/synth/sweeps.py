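"""Synthetic single-channel sweep sets.

Emulates the cell-attached acquisition chain: Markov-gated unitary
currents of ~1-2 pA riding on a noisy baseline, sampled at 10 kHz after a
2 kHz low-pass filter, collected as consecutive pulses from a holding
potential.  Channel gating is simulated in continuous time (exponential
dwell times) and then sampled onto the acquisition grid, so dwell-time
statistics carry no time-step bias.  The true open-count path of every
sweep is retained alongside the signal as ground truth for estimator
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as sps

from ltccmicro.markov import MarkovSpec, two_state_spec
from ltccmicro.protocols import ClampProtocol

__all__ = ["SweepGenConfig", "SweepSet", "gen_sweep_set", "DEFAULT_UNITARY_PA"]

#: Default unitary current at −6.7 mV, pA (≈18 pS with reversal near +60 mV).
DEFAULT_UNITARY_PA = -1.2


@dataclass(frozen=True)
class SweepGenConfig:
    """Configuration of a synthetic sweep-set generator.

    ``gating`` is a :class:`~ltccmicro.markov.MarkovSpec`; use
    :func:`~ltccmicro.markov.two_state_spec` for a simple open/closed
    channel with constant rates.
    """

    n_sweeps: int = 50
    sweep_duration: float | None = None  # s; default: protocol sweep length
    sampling_rate: float = 10_000.0  # Hz
    n_channels: int = 1
    gating: MarkovSpec = field(default_factory=lambda: two_state_spec(0.1, 0.9))
    unitary_amplitude: float = DEFAULT_UNITARY_PA  # pA, inward negative
    noise_sd: float = 0.15  # pA
    lowpass_cutoff: float = 2_000.0  # Hz
    ca: float = 1.0  # µM seen by Ca-dependent gates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.sweep_duration is not None and self.sweep_duration <= 0:
            raise ValueError("sweep_duration must be positive")
        if self.sampling_rate <= 2 * self.lowpass_cutoff:
            raise ValueError("sampling_rate must exceed twice the low-pass cutoff")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


@dataclass
class SweepSet:
    """A stack of single-channel current sweeps plus acquisition metadata.

    ``current`` is (n_sweeps, n_samples) in pA; ``truth_state`` the
    simultaneous true open-channel count per sample.
    """

    current: np.ndarray
    truth_state: np.ndarray
    sampling_rate: float
    protocol: ClampProtocol
    n_channels: int
    unitary_amplitude: float
    config: SweepGenConfig | None = None

    @property
    def n_sweeps(self) -> int:
        return self.current.shape[0]

    @property
    def n_samples(self) -> int:
        return self.current.shape[1]

    def step_window(self) -> tuple[int, int]:
        return self.protocol.step_window(self.sampling_rate)

    def true_po(self) -> float:
        """Ground-truth single-channel open probability over the step window."""
        a, b = self.step_window()
        return float(self.truth_state[:, a:b].mean() / self.n_channels)

    def true_sweep_open_fractions(self) -> np.ndarray:
        """Per-sweep summed open fraction (NPo per sweep) over the step window."""
        a, b = self.step_window()
        return self.truth_state[:, a:b].mean(axis=1)

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("current", data=self.current, compression="gzip")
            f.create_dataset("truth_state", data=self.truth_state, compression="gzip")
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["n_channels"] = self.n_channels
            f.attrs["unitary_amplitude"] = self.unitary_amplitude
            f.attrs["holding_potential"] = self.protocol.holding_potential
            f.attrs["step_potentials"] = list(self.protocol.step_potentials)
            f.attrs["pulse_duration"] = self.protocol.pulse_duration
            f.attrs["pre_step"] = self.protocol.pre_step
            f.attrs["post_step"] = self.protocol.post_step

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "SweepSet":
        with h5py.File(path, "r") as f:
            proto = ClampProtocol(
                holding_potential=float(f.attrs["holding_potential"]),
                step_potentials=tuple(float(v) for v in f.attrs["step_potentials"]),
                pulse_duration=float(f.attrs["pulse_duration"]),
                pre_step=float(f.attrs["pre_step"]),
                post_step=float(f.attrs["post_step"]),
            )
            return cls(
                current=f["current"][...],
                truth_state=f["truth_state"][...],
                sampling_rate=float(f.attrs["sampling_rate"]),
                protocol=proto,
                n_channels=int(f.attrs["n_channels"]),
                unitary_amplitude=float(f.attrs["unitary_amplitude"]),
            )


def _sample_channel_path(
    rng: np.random.Generator,
    alpha: np.ndarray,
    beta: np.ndarray,
    p_open0: np.ndarray,
    duration_ms: float,
    sampling_rate: float,
) -> np.ndarray:
    """Continuous-time multi-gate path sampled onto the acquisition grid.

    Returns a 0/1 open indicator per sample (open = all gates permissive).
    """
    n_g = alpha.size
    n_samples = int(round(duration_ms / 1000.0 * sampling_rate))
    dt_ms = 1000.0 / sampling_rate
    state = (rng.random(n_g) < p_open0).astype(np.int64)
    out = np.zeros(n_samples, dtype=np.int8)
    t = 0.0
    idx = 0
    while idx < n_samples:
        rates = np.where(state == 1, beta, alpha)
        total = rates.sum()
        if total <= 0:
            if state.all():
                out[idx:] = 1
            break
        dwell = rng.exponential(1.0 / total)
        t_next = t + dwell
        if state.all():
            # mark samples whose sample time falls inside [t, t_next)
            j = min(int(np.ceil(t_next / dt_ms)), n_samples)
            out[idx:j] = 1
        idx = min(int(np.ceil(t_next / dt_ms)), n_samples)
        # switch one gate, chosen proportionally to its rate
        r = rng.random() * total
        acc = 0.0
        for g in range(n_g):
            acc += rates[g]
            if r < acc:
                state[g] = 1 - state[g]
                break
        t = t_next
    return out


def gen_sweep_set(config: SweepGenConfig, protocol: ClampProtocol | None = None) -> SweepSet:
    """Generate a synthetic sweep set under ``protocol``.

    Channel openings occur only during the depolarizing step (channels are
    deactivated at the holding potential); the recorded current is
    ``open_count * unitary_amplitude`` plus low-pass-filtered Gaussian
    noise.  Bit-reproducible under ``config.seed``.
    """
    protocol = protocol or ClampProtocol(n_pulses=config.n_sweeps)
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    duration = config.sweep_duration if config.sweep_duration is not None else protocol.sweep_duration
    n_samples = int(round(duration * fs))
    a, b = protocol.step_window(fs)
    b = min(b, n_samples)
    step_ms = (b - a) * 1000.0 / fs
    v_step = protocol.step_potentials[0]

    spec = config.gating
    rt = spec.rate_table(v_step, config.ca)
    alpha = np.ascontiguousarray(rt[:, 0])
    beta = np.ascontiguousarray(rt[:, 1])
    with np.errstate(invalid="ignore"):
        p0 = np.where(alpha + beta > 0, alpha / np.maximum(alpha + beta, 1e-300), 0.0)

    truth = np.zeros((config.n_sweeps, n_samples), dtype=np.int16)
    for s in range(config.n_sweeps):
        counts = np.zeros(b - a, dtype=np.int16)
        for _ in range(config.n_channels):
            counts += _sample_channel_path(rng, alpha, beta, p0, step_ms, fs)[: b - a]
        truth[s, a:b] = counts

    current = truth.astype(np.float64) * config.unitary_amplitude
    if config.noise_sd > 0:
        noise = rng.standard_normal(current.shape)
        # 4-pole low-pass Bessel at the stated corner frequency
        sos = sps.bessel(4, config.lowpass_cutoff, fs=fs, output="sos", norm="mag")
        noise = sps.sosfilt(sos, noise, axis=1)
        # restore the requested SD after filtering
        noise *= config.noise_sd / noise.std()
        current = current + noise
    return SweepSet(
        current=current,
        truth_state=truth,
        sampling_rate=fs,
        protocol=protocol,
        n_channels=config.n_channels,
        unitary_amplitude=config.unitary_amplitude,
        config=config,
    )
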