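"""Voltage-clamp and pacing protocol definitions.

All potentials are stored *after* liquid-junction-potential (LJP)
correction: cell-attached recordings with the K-gluconate bath / Ba2+
pipette solution pair carry a −16.7 mV junction offset, so a commanded
−80 mV corresponds to a true membrane potential of −96.7 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Liquid junction potential of the recording solutions, mV.
LJP_MV = -16.7

#: Corrected holding potential used for all single-channel protocols, mV.
HOLDING_MV = -96.7

#: Corrected test potential used for open-probability measurement, mV.
PO_STEP_MV = -6.7


def correct_junction_potential(commanded_mv: float, ljp_mv: float = LJP_MV) -> float:
    """Convert a commanded pipette potential to the LJP-corrected value.

    Parameters
    ----------
    commanded_mv : float
        Potential commanded by the amplifier, mV.
    ljp_mv : float
        Liquid junction potential, mV (default −16.7).

    Returns
    -------
    float
        Corrected potential ``commanded_mv + ljp_mv``; e.g. a commanded
        −80 mV becomes −96.7 mV.
    """
    return commanded_mv + ljp_mv


def iv_step_potentials() -> list[float]:
    """Corrected test potentials of the I-V protocol: −36.7 … +23.3 mV in 10 mV steps."""
    return [round(-36.7 + 10.0 * k, 1) for k in range(7)]


@dataclass(frozen=True)
class ClampProtocol:
    """A square-step voltage-clamp protocol (corrected potentials).

    The default is the single-channel open-probability protocol: hold at
    −96.7 mV, 50 consecutive 1 s pulses to −6.7 mV.
    """

    holding_potential: float = HOLDING_MV  # mV
    step_potentials: tuple[float, ...] = (PO_STEP_MV,)  # mV
    pulse_duration: float = 1.0  # s
    n_pulses: int = 50
    junction_potential: float = LJP_MV  # mV
    pre_step: float = 0.1  # s of holding baseline recorded before each pulse
    post_step: float = 0.05  # s of holding recorded after each pulse

    def __post_init__(self) -> None:
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if not self.step_potentials:
            raise ValueError("at least one step potential is required")

    @property
    def sweep_duration(self) -> float:
        """Total duration of one sweep (baseline + pulse + tail), s."""
        return self.pre_step + self.pulse_duration + self.post_step

    def step_window(self, sampling_rate: float) -> tuple[int, int]:
        """Sample-index window [start, stop) of the depolarizing pulse."""
        start = int(round(self.pre_step * sampling_rate))
        stop = int(round((self.pre_step + self.pulse_duration) * sampling_rate))
        return start, stop


def iv_protocol() -> ClampProtocol:
    """The incremental I-V protocol: 10 mV steps from −36.7 to +23.3 mV."""
    return ClampProtocol(step_potentials=tuple(iv_step_potentials()), n_pulses=3)


@dataclass(frozen=True)
class PacingProtocol:
    """The skipped-beat pacing protocol.

    Two stimuli at 1 s intervals, a pause standing for two skipped beats,
    then regular 1 Hz pacing resumed 4 s after the start of the protocol.
    """

    cycle_length: float = 1000.0  # ms
    n_initial_beats: int = 2
    n_skipped_beats: int = 2
    n_resumed_beats: int = 4
    stim_amplitude: float = -80.0  # µA/µF
    stim_duration: float = 0.5  # ms

    def stimulus_times(self) -> list[float]:
        """Stimulus onset times in ms from the start of the recorded protocol."""
        times = [i * self.cycle_length for i in range(self.n_initial_beats)]
        resume = (self.n_initial_beats + self.n_skipped_beats) * self.cycle_length
        times += [resume + i * self.cycle_length for i in range(self.n_resumed_beats)]
        return times

    @property
    def total_duration(self) -> float:
        """Recorded protocol length, ms (one full cycle after the last stimulus)."""
        return self.stimulus_times()[-1] + self.cycle_length
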