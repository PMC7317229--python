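"""Disease-variant myocyte models and their simulation protocols.

Builds control / ICM / DCM human ventricular myocyte variants on the
microdomain-partitioned ionic model:

- **control** — T-tubule integrity 1, LTCC split between TT and crest
  from the control occurrence ratio, no phosphorylation;
- **ICM** (ischemic) — T-tubule degradation TTD = 0.65, TT fraction 0.45
  (occurrence ratio 0.8), 70% of TT channels PKA-phosphorylated, heart-
  failure remodeling of the non-LTCC currents;
- **DCM** (dilated) — TT fraction from the DCM occurrences, all crest
  channels CaMKII-phosphorylated, the same heart-failure remodeling.

In both diseases the whole-cell LTCC current is rescaled by a correction
factor so its voltage-clamp peak matches control (remodeling does not
change peak I_CaL in human myocytes), and in-silico kinase block (H-89 /
KN-93 analogues) zeroes the respective phosphorylation effect.

Protocols: the experimental voltage clamp (−96.7 → −6.7 mV) with
per-domain current decomposition, and the skipped-beat pacing protocol
(two beats at 1 Hz, two skipped, 1 Hz resumed) with APD90 and
early-afterdepolarization (EAD) detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ltccmicro import ord_model as om
from ltccmicro.protocols import PacingProtocol

__all__ = [
    "HFRemodeling",
    "CellParams",
    "ClampResult",
    "PacingResult",
    "EADEvent",
    "compute_ttd",
    "domain_fraction_from_occurrence",
    "build_cell_variant",
    "compute_current_correction",
    "run_voltage_clamp",
    "run_pacing",
    "detect_eads",
    "measure_apd",
    "prepaced_state",
    "CONTROL_OCCURRENCE",
    "ICM_OCCURRENCE",
    "DCM_OCCURRENCE",
]

#: (TT, crest) LTCC occurrence percentages per group, from the recordings table.
CONTROL_OCCURRENCE = (25.8, 10.3)
ICM_OCCURRENCE = (20.0, 25.0)
DCM_OCCURRENCE = (22.6, 27.5)

#: T-tubule integrity of the ICM cell (mean of disease:control TT-density
#: and Z-groove ratios).
ICM_TTD = 0.65

_CTRL_RATIO = CONTROL_OCCURRENCE[0] / CONTROL_OCCURRENCE[1]
_CTRL_F_TT = _CTRL_RATIO / (1.0 + _CTRL_RATIO)


@dataclass(frozen=True)
class HFRemodeling:
    """Named scalings of the non-LTCC currents in failing myocytes.

    An editable approximation of the heart-failure ionic remodeling set
    (reduced SERCA uptake and inward rectifier / transient outward /
    rapid delayed rectifier conductances, increased Na-Ca exchange and
    late Na current), with defaults chosen to produce the action-
    potential prolongation characteristic of failing human myocytes.
    """

    serca: float = 0.5
    ncx: float = 1.75
    gk1: float = 0.68
    gto: float = 0.6
    gnal: float = 2.0
    gkr: float = 0.25
    gks: float = 0.8
    jrel: float = 0.8

    @classmethod
    def none(cls) -> "HFRemodeling":
        return cls(serca=1.0, ncx=1.0, gk1=1.0, gto=1.0, gnal=1.0, gkr=1.0, gks=1.0, jrel=1.0)


@dataclass(frozen=True)
class CellParams:
    """A disease-variant myocyte configuration."""

    variant: str  # control | ICM | DCM
    celltype: str = "endo"  # endo | epi
    ttd: float = 1.0
    f_tt: float = _CTRL_F_TT
    ratio_tt_crest: float = _CTRL_RATIO
    pka_fraction: float = 0.0
    camkii_crest: float = 0.0
    pka_block: bool = False
    camkii_block: bool = False
    correction_factor: float = 1.0
    hf_remodeling: HFRemodeling = field(default_factory=HFRemodeling.none)

    def __post_init__(self) -> None:
        for name in ("ttd", "f_tt", "pka_fraction", "camkii_crest"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if abs(self.f_tt - self.ratio_tt_crest / (1.0 + self.ratio_tt_crest)) > 1e-6:
            raise ValueError("f_tt must equal ratio/(1+ratio)")

    def to_vector(self) -> np.ndarray:
        p = om.default_params(self.celltype)
        p[om.P.F_TT] = self.f_tt
        p[om.P.TTD] = self.ttd
        p[om.P.PKA_FRACTION] = self.pka_fraction
        p[om.P.CAMKII_CREST] = 0.0 if self.camkii_block else self.camkii_crest
        p[om.P.CORRECTION] = self.correction_factor
        if self.pka_block:
            # blocked kinase: phosphorylated channels behave like base channels
            p[om.P.PKA_CURRENT_FACTOR] = 1.0
            p[om.P.PKA_ACT_SHIFT] = 0.0
            p[om.P.PKA_INACT_SHIFT] = 0.0
            p[om.P.PKA_TAU_FACTOR] = 1.0
        hf = self.hf_remodeling
        p[om.P.SERCA_SCALE] = hf.serca
        p[om.P.NCX_SCALE] = hf.ncx
        p[om.P.GK1_SCALE] = hf.gk1
        p[om.P.GTO_SCALE] = hf.gto
        p[om.P.GNAL_SCALE] = hf.gnal
        p[om.P.GKR_SCALE] = hf.gkr
        p[om.P.GKS_SCALE] = hf.gks
        p[om.P.JREL_SCALE] = hf.jrel
        return p


# ---------------------------------------------------------------------------
# Model-construction equations
# ---------------------------------------------------------------------------

def compute_ttd(tt_density_ratio: float, zgroove_ratio: float) -> float:
    """T-tubule integrity: the mean of the disease:control TT-density and
    Z-groove-index ratios (1 = healthy, 0 = complete loss)."""
    if tt_density_ratio < 0 or zgroove_ratio < 0:
        raise ValueError("ratios must be non-negative")
    if tt_density_ratio == 0 and zgroove_ratio == 0:
        return 0.0
    if tt_density_ratio < 0 or zgroove_ratio < 0:
        raise ValueError("ratios must be positive")
    return 0.5 * (tt_density_ratio + zgroove_ratio)


def domain_fraction_from_occurrence(occ_tt: float, occ_crest: float) -> tuple[float, float]:
    """LTCC distribution from occurrence percentages.

    The TT:crest channel-number ratio equals the ratio of the TT and
    crest occurrence percentages; the TT fraction is ratio/(1+ratio).
    Returns ``(ratio_tt_crest, f_tt)``.
    """
    if occ_crest <= 0:
        raise ValueError("crest occurrence must be positive (ratio undefined)")
    if occ_tt < 0:
        raise ValueError("occurrences must be non-negative")
    ratio = occ_tt / occ_crest
    return ratio, ratio / (1.0 + ratio)


def build_cell_variant(
    variant: str,
    celltype: str = "endo",
    pka_block: bool = False,
    camkii_block: bool = False,
    hf_remodeling: HFRemodeling | None = None,
) -> CellParams:
    """Assemble the parameter set of a control / ICM / DCM myocyte.

    The correction factor is left at 1; apply
    :func:`compute_current_correction` to match the control peak.
    """
    if celltype not in ("endo", "epi"):
        raise ValueError(f"unknown celltype {celltype!r}")
    if variant == "control":
        ratio, f_tt = domain_fraction_from_occurrence(*CONTROL_OCCURRENCE)
        return CellParams(
            variant=variant, celltype=celltype, ttd=1.0,
            f_tt=f_tt, ratio_tt_crest=ratio,
            hf_remodeling=HFRemodeling.none(),
        )
    if variant == "ICM":
        ratio, f_tt = domain_fraction_from_occurrence(*ICM_OCCURRENCE)
        return CellParams(
            variant=variant, celltype=celltype, ttd=ICM_TTD,
            f_tt=f_tt, ratio_tt_crest=ratio,
            pka_fraction=0.7, pka_block=pka_block, camkii_block=camkii_block,
            hf_remodeling=hf_remodeling or HFRemodeling(),
        )
    if variant == "DCM":
        ratio, f_tt = domain_fraction_from_occurrence(*DCM_OCCURRENCE)
        return CellParams(
            variant=variant, celltype=celltype, ttd=1.0,
            f_tt=f_tt, ratio_tt_crest=ratio,
            camkii_crest=1.0, pka_block=pka_block, camkii_block=camkii_block,
            hf_remodeling=hf_remodeling or HFRemodeling(),
        )
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Voltage clamp
# ---------------------------------------------------------------------------

@dataclass
class ClampResult:
    """Per-domain LTCC currents under the −96.7 → −6.7 mV clamp."""

    time: np.ndarray  # ms, 0 at step onset
    i_cal_tt: np.ndarray  # µA/µF
    i_cal_crest: np.ndarray

    @property
    def i_cal_total(self) -> np.ndarray:
        return self.i_cal_tt + self.i_cal_crest

    def peak(self, component: str = "total") -> float:
        trace = getattr(self, f"i_cal_{component}")
        return float(trace.min())  # inward negative

    def decay_metric(self, component: str = "total") -> float:
        """Time (ms) from the peak to 50% of the peak magnitude."""
        trace = np.asarray(getattr(self, f"i_cal_{component}"))
        k = int(np.argmin(trace))
        peak = trace[k]
        if peak >= 0:
            return math.nan
        target = 0.5 * peak
        after = trace[k:]
        above = np.where(after >= target)[0]
        if above.size == 0:
            return math.nan
        j = above[0]
        if j == 0:
            return 0.0
        # linear interpolation between samples j-1 and j
        t0, t1 = self.time[k + j - 1], self.time[k + j]
        v0, v1 = after[j - 1], after[j]
        frac = (target - v0) / (v1 - v0) if v1 != v0 else 0.0
        return float(t0 + frac * (t1 - t0) - self.time[k])


def run_voltage_clamp(
    params: CellParams,
    v_hold: float = -96.7,
    v_step: float = -6.7,
    hold_ms: float = 2000.0,
    step_ms: float = 500.0,
    dt: float = 0.01,
) -> ClampResult:
    """Clamp protocol of the experiments: hold, then a depolarizing step.

    Returns the TT and crest I_CaL components over the step (time zeroed
    at step onset); the total is their sum by construction.
    """
    if step_ms < 300.0:
        raise ValueError("step must be at least 300 ms")
    p = params.to_vector()
    y = om.initial_state()
    t, v, itt, icr = om.integrate(
        y, p, hold_ms + step_ms, dt=dt, record_every=10,
        clamp=(v_hold, v_step, hold_ms, hold_ms + step_ms),
    )
    sel = t >= hold_ms
    return ClampResult(time=t[sel] - hold_ms, i_cal_tt=itt[sel], i_cal_crest=icr[sel])


def compute_current_correction(
    params: CellParams,
    reference: CellParams,
    tol: float = 0.01,
    max_iter: int = 20,
) -> CellParams:
    """Correction factor matching the variant's clamp peak I_CaL to control.

    Iteratively rescales the whole-cell LTCC current until the peak under
    the standard clamp is within ``tol`` (relative) of the reference
    peak.  Returns a copy of ``params`` with the factor stored.
    """
    if reference.variant != "control":
        raise ValueError("reference must be the control variant")
    ref_peak = run_voltage_clamp(reference).peak()
    out = params
    for _ in range(max_iter):
        peak = run_voltage_clamp(out).peak()
        ratio = peak / ref_peak
        if abs(ratio - 1.0) <= tol:
            return out
        out = replace(out, correction_factor=out.correction_factor / ratio)
    raise RuntimeError("current correction did not converge")


# ---------------------------------------------------------------------------
# Pacing, EADs, APD
# ---------------------------------------------------------------------------

@dataclass
class EADEvent:
    time: float  # ms, absolute
    amplitude: float  # mV of secondary depolarization
    beat: int


@dataclass
class PacingResult:
    time: np.ndarray  # ms
    v: np.ndarray  # mV
    stimulus_times: np.ndarray  # ms
    apd90: list[float]  # per captured beat (nan if non-repolarizing)
    ead_events: list[EADEvent]

    @property
    def n_eads(self) -> int:
        return len(self.ead_events)


_PREPACE_CACHE: dict = {}


def prepaced_state(
    params: CellParams,
    n_beats: int = 100,
    cycle_ms: float = 1000.0,
    dt: float = 0.01,
) -> np.ndarray:
    """Quasi-steady state after ``n_beats`` of 1 Hz pacing (cached)."""
    key = (params.to_vector().tobytes(), n_beats, cycle_ms, dt)
    if key not in _PREPACE_CACHE:
        y = om.initial_state()
        p = params.to_vector()
        stim = np.arange(n_beats) * cycle_ms + 10.0
        om.integrate(y, p, n_beats * cycle_ms, dt=dt, record_every=1000, stim_starts=stim)
        _PREPACE_CACHE[key] = y.copy()
    return _PREPACE_CACHE[key].copy()


def run_pacing(
    params: CellParams,
    pacing: PacingProtocol | None = None,
    prepace_beats: int = 100,
    dt: float = 0.01,
) -> PacingResult:
    """Run the skipped-beat protocol from a pre-paced state."""
    pacing = pacing or PacingProtocol()
    y = prepaced_state(params, n_beats=prepace_beats, cycle_ms=pacing.cycle_length, dt=dt)
    p = params.to_vector()
    stim = np.array(pacing.stimulus_times()) + 10.0
    t, v, _, _ = om.integrate(
        y, p, pacing.total_duration, dt=dt, record_every=10,
        stim_starts=stim, stim_dur=pacing.stim_duration, stim_amp=pacing.stim_amplitude,
    )
    eads = detect_eads(t, v, stim)
    apd = [measure_apd(t, v, (s, s + pacing.cycle_length)) for s in stim]
    return PacingResult(time=t, v=v, stimulus_times=stim, apd90=apd, ead_events=eads)


def detect_eads(
    t: np.ndarray,
    v: np.ndarray,
    beat_starts: np.ndarray,
    repol_level: float = -40.0,
    min_amplitude: float = 2.0,
) -> list[EADEvent]:
    """Early afterdepolarizations in a voltage trace.

    An EAD is a negative-to-positive dV/dt sign change after the AP peak
    and before repolarization to ``repol_level``, followed by a secondary
    depolarization of at least ``min_amplitude`` mV.  Returns events with
    their time (at the local minimum) and amplitude.
    """
    t = np.asarray(t)
    v = np.asarray(v)
    beat_starts = np.sort(np.asarray(beat_starts, dtype=float))
    events: list[EADEvent] = []
    for b, start in enumerate(beat_starts):
        end = beat_starts[b + 1] if b + 1 < beat_starts.size else t[-1]
        sel = (t >= start) & (t <= end)
        if sel.sum() < 5:
            continue
        tb = t[sel]
        vb = v[sel]
        k_peak = int(np.argmax(vb))
        # scan the repolarization phase above repol_level
        i = k_peak
        n = vb.size
        while i < n - 1:
            if vb[i] < repol_level:
                break
            # local minimum: falling then rising
            if vb[i] <= vb[i - 1] and vb[i] < vb[i + 1]:
                j = i
                while j < n - 1 and vb[j + 1] >= vb[j]:
                    j += 1
                rise = vb[j] - vb[i]
                if rise >= min_amplitude and vb[i] > repol_level:
                    events.append(EADEvent(time=float(tb[i]), amplitude=float(rise), beat=b))
                    i = j
            i += 1
    return events


def measure_apd(
    t: np.ndarray,
    v: np.ndarray,
    beat_window: tuple[float, float],
    level: float = 90.0,
) -> float:
    """Action-potential duration at ``level``% repolarization.

    Measured from the maximum upstroke velocity to the linear-interpolated
    crossing of peak − level% of the amplitude (amplitude = peak − value
    at the window start).  Returns NaN for a non-repolarizing beat.
    """
    t = np.asarray(t)
    v = np.asarray(v)
    sel = (t >= beat_window[0]) & (t <= beat_window[1])
    tb, vb = t[sel], v[sel]
    if tb.size < 5:
        return math.nan
    dvdt = np.gradient(vb, tb)
    k_up = int(np.argmax(dvdt))
    v_rest = vb[0]
    v_peak = float(vb.max())
    threshold = v_peak - level / 100.0 * (v_peak - v_rest)
    k_peak = int(np.argmax(vb))
    after = vb[k_peak:]
    below = np.where(after <= threshold)[0]
    if below.size == 0:
        return math.nan
    j = below[0]
    if j == 0:
        return float(tb[k_peak] - tb[k_up])
    t0, t1 = tb[k_peak + j - 1], tb[k_peak + j]
    v0, v1 = after[j - 1], after[j]
    frac = (threshold - v0) / (v1 - v0) if v1 != v0 else 0.0
    return float(t0 + frac * (t1 - t0) - tb[k_up])
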