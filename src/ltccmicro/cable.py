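"""1D monodomain tissue cable: do cellular EADs propagate in tissue?

A desk-scale reduction of the whole-heart question: a cable of coupled
myocytes, uniformly control or with a central patch of a disease
variant, paced with the skipped-beat protocol.  The outcome is an
ordinal classification —

``none``
    activations appear only in response to stimuli;
``local_ead``
    the disease patch develops EADs but electrotonic load keeps them
    subthreshold distally (source-sink mismatch);
``triggered_propagation``
    a non-stimulated wave reaches the far end of the cable.

Reaction-diffusion integration uses operator splitting: the ionic model
advances each cell (Rush-Larsen / Euler), then an explicit finite-
difference diffusion step couples the voltages, with no-flux ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from ltccmicro import ord_model as om
from ltccmicro import myocyte as myo
from ltccmicro.protocols import PacingProtocol

__all__ = [
    "CableConfig",
    "CableResult",
    "run_cable",
    "classify_propagation",
    "conduction_velocity",
]


@dataclass(frozen=True)
class CableConfig:
    """Configuration of the 1D monodomain cable."""

    n_cells: int = 100
    dx: float = 0.01  # cm (100 µm cell pitch)
    diffusion: float = 0.0017  # cm²/ms, tuned for ~50 cm/s control conduction
    patch_variant: str | None = None  # disease variant of the central patch
    patch_size: int = 20  # cells
    pka_block: bool = False
    camkii_block: bool = False
    celltype: str = "endo"
    dt: float = 0.005  # ms
    stim_cells: int = 5  # stimulated edge cells
    stim_amplitude: float = -80.0  # µA/µF
    stim_duration: float = 2.0  # ms
    record_every: int = 50  # steps between voltage snapshots
    prepace_beats: int = 100
    hf_remodeling: myo.HFRemodeling | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 20:
            raise ValueError("n_cells must be >= 20")
        if self.diffusion <= 0:
            raise ValueError("diffusion must be positive")
        if self.patch_size > self.n_cells:
            raise ValueError("patch cannot exceed the cable")

    def patch_slice(self) -> slice:
        mid = self.n_cells // 2
        return slice(mid - self.patch_size // 2, mid - self.patch_size // 2 + self.patch_size)

    def cfl(self) -> float:
        return self.diffusion * self.dt / self.dx**2


@dataclass
class CableResult:
    time: np.ndarray  # ms
    v: np.ndarray  # (n_cells, n_times) mV
    stimulus_times: np.ndarray  # ms
    config: CableConfig

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("v", data=self.v, compression="gzip")
            f.create_dataset("time", data=self.time)
            f.attrs["stimulus_times"] = self.stimulus_times
            f.attrs["n_cells"] = self.config.n_cells
            f.attrs["dx_cm"] = self.config.dx


@njit(cache=True)
def _run_cable_kernel(Y, params, dt, n_steps, record_every, D_over_dx2,
                      stim_starts, stim_dur, stim_amp, n_stim_cells):  # pragma: no cover
    n_cells = Y.shape[0]
    n_rec = n_steps // record_every + 1
    v_rec = np.empty((n_cells, n_rec))
    t_rec = np.empty(n_rec)
    r = 0
    for s in range(n_steps + 1):
        t = s * dt
        istim = 0.0
        for k in range(stim_starts.size):
            if stim_starts[k] <= t < stim_starts[k] + stim_dur:
                istim = stim_amp
        if s % record_every == 0 and r < n_rec:
            for c in range(n_cells):
                v_rec[c, r] = Y[c, 0]
            t_rec[r] = t
            r += 1
        # reaction step
        for c in range(n_cells):
            stim_c = istim if c < n_stim_cells else 0.0
            om._step(Y[c], params[c], dt, stim_c, False, 0.0)
        # explicit diffusion step with no-flux boundaries
        vnew = np.empty(n_cells)
        for c in range(n_cells):
            vl = Y[c - 1, 0] if c > 0 else Y[1, 0]
            vr = Y[c + 1, 0] if c < n_cells - 1 else Y[n_cells - 2, 0]
            vnew[c] = Y[c, 0] + dt * D_over_dx2 * (vl - 2.0 * Y[c, 0] + vr)
        for c in range(n_cells):
            Y[c, 0] = vnew[c]
    return t_rec[:r], v_rec[:, :r]


def run_cable(
    config: CableConfig,
    pacing: PacingProtocol | None = None,
) -> CableResult:
    """Run the skipped-beat protocol on the cable.

    Cells start from their single-cell pre-paced states (control state
    for control cells, corrected disease state in the patch).  Raises
    before integrating if the explicit diffusion step violates the CFL
    stability bound.
    """
    if config.cfl() > 0.5:
        raise ValueError(
            f"CFL violation: D*dt/dx^2 = {config.cfl():.3f} > 0.5; reduce dt or refine dx"
        )
    pacing = pacing or PacingProtocol()
    ctrl = myo.build_cell_variant("control", celltype=config.celltype)
    params_ctrl = ctrl.to_vector()
    y_ctrl = myo.prepaced_state(ctrl, n_beats=config.prepace_beats,
                                cycle_ms=pacing.cycle_length)

    Y = np.tile(y_ctrl, (config.n_cells, 1))
    params = np.tile(params_ctrl, (config.n_cells, 1))
    if config.patch_variant and config.patch_variant != "control":
        kw = {}
        disease = myo.build_cell_variant(
            config.patch_variant, celltype=config.celltype,
            pka_block=config.pka_block, camkii_block=config.camkii_block,
            hf_remodeling=config.hf_remodeling,
        )
        disease = myo.compute_current_correction(disease, ctrl)
        y_dis = myo.prepaced_state(disease, n_beats=config.prepace_beats,
                                   cycle_ms=pacing.cycle_length)
        sl = config.patch_slice()
        Y[sl] = y_dis
        params[sl] = disease.to_vector()

    stim = np.array(pacing.stimulus_times()) + 10.0
    n_steps = int(round(pacing.total_duration / config.dt))
    t, v = _run_cable_kernel(
        Y, params, config.dt, n_steps, config.record_every,
        config.diffusion / config.dx**2,
        stim, config.stim_duration, config.stim_amplitude, config.stim_cells,
    )
    return CableResult(time=t, v=v, stimulus_times=stim, config=config)


def _activation_times(t: np.ndarray, v_cell: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Upstroke times: upward crossings of ``threshold`` separated by a
    refractory gap."""
    above = v_cell > threshold
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if idx.size == 0:
        return np.empty(0)
    times = t[idx]
    keep = [times[0]]
    for x in times[1:]:
        if x - keep[-1] > 100.0:  # ms refractory separation
            keep.append(x)
    return np.array(keep)


def conduction_velocity(result: CableResult) -> float:
    """Conduction velocity (cm/s) of the first paced wave over the
    mid-section of the cable."""
    cfg = result.config
    c0, c1 = int(cfg.n_cells * 0.3), int(cfg.n_cells * 0.7)
    t0 = _activation_times(result.time, result.v[c0])
    t1 = _activation_times(result.time, result.v[c1])
    if t0.size == 0 or t1.size == 0 or t1[0] <= t0[0]:
        return math.nan
    dist_cm = (c1 - c0) * cfg.dx
    return dist_cm / (t1[0] - t0[0]) * 1000.0


def classify_propagation(
    result: CableResult,
    stim_window_ms: float = 200.0,
) -> str:
    """Classify the cable outcome: none, local_ead, triggered_propagation.

    A distal activation (95% along the cable) with no stimulus within
    ``stim_window_ms`` before it is a triggered propagated beat; EADs in
    the patch centre (or mid-cable if uniform) without such an activation
    are a local EAD; otherwise the outcome is quiet.
    """
    cfg = result.config
    distal = min(cfg.n_cells - 3, int(cfg.n_cells * 0.95))
    act = _activation_times(result.time, result.v[distal])
    stim = result.stimulus_times
    for at in act:
        if not np.any((stim <= at) & (at - stim <= stim_window_ms)):
            return "triggered_propagation"
    mid = cfg.n_cells // 2
    eads = myo.detect_eads(result.time, result.v[mid], stim)
    if eads:
        return "local_ead"
    return "none"
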